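"""Synthetic players and round-level tracking logs with known ground truth.

Players are drawn from two involvement groups whose latent parameters
(stop hazards, stake-change policy, response-time model, session counts,
stake levels) are configurable per group.  Game outcomes come from the
round simulator in :mod:`chasekit.game`; stopping is modelled as
outcome-conditional Bernoulli hazards (an optional finite-bankroll mode
forces a stop when funds no longer cover the stake), stake changes as
outcome-conditional ladder steps, and first-column response times as
lognormal with an additive log-scale shift after losses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import game as _game
from .game import DEFAULT_POINT_TABLE, DEFAULT_STAKE_SCHEDULE, PointTable, StakeSchedule

__all__ = [
    "SimConfigError",
    "PlayerProfile",
    "GameSettings",
    "SimConfig",
    "default_sim_config",
    "sample_profiles",
    "simulate_player",
    "generate_dataset",
]


class SimConfigError(ValueError):
    """Raised for an improper simulation configuration."""


# ---------------------------------------------------------------------------
# distribution specs
# ---------------------------------------------------------------------------

def _sample_spec(spec: Any, rng: np.random.Generator, size: int):
    """Draw from a distribution spec.

    A bare number is a point mass.  Dict forms:
    ``{"dist": "normal", "mean": m, "sd": s, ["lo": a, "hi": b]}`` (clipped),
    ``{"dist": "uniform", "lo": a, "hi": b}``,
    ``{"dist": "lognormal", "meanlog": m, "sdlog": s}``,
    ``{"dist": "choice", "values": [...], ["probs": [...]]}``.
    """
    if isinstance(spec, (int, float)) and not isinstance(spec, bool):
        return np.full(size, float(spec))
    if not isinstance(spec, Mapping) or "dist" not in spec:
        raise SimConfigError(f"not a distribution spec: {spec!r}")
    kind = spec["dist"]
    if kind == "normal":
        sd = float(spec["sd"])
        if sd < 0:
            raise SimConfigError("normal sd must be >= 0")
        x = rng.normal(float(spec["mean"]), sd, size)
        if "lo" in spec or "hi" in spec:
            x = np.clip(x, spec.get("lo", -np.inf), spec.get("hi", np.inf))
        return x
    if kind == "uniform":
        lo, hi = float(spec["lo"]), float(spec["hi"])
        if hi < lo:
            raise SimConfigError("uniform needs lo <= hi")
        return rng.uniform(lo, hi, size)
    if kind == "lognormal":
        sdlog = float(spec["sdlog"])
        if sdlog < 0:
            raise SimConfigError("lognormal sdlog must be >= 0")
        return rng.lognormal(float(spec["meanlog"]), sdlog, size)
    if kind == "choice":
        values = np.asarray(spec["values"], dtype=float)
        probs = spec.get("probs")
        if probs is not None:
            probs = np.asarray(probs, dtype=float)
            if probs.min() < 0 or abs(probs.sum() - 1) > 1e-9 or len(probs) != len(values):
                raise SimConfigError(f"improper choice probabilities {probs!r}")
        return rng.choice(values, size=size, p=probs)
    raise SimConfigError(f"unknown distribution kind {kind!r}")


def _validate_step_dist(steps: Mapping[int, float], name: str) -> dict[int, float]:
    out = {int(k): float(v) for k, v in steps.items()}
    total = sum(out.values())
    if any(v < 0 for v in out.values()) or abs(total - 1.0) > 1e-9:
        raise SimConfigError(f"{name}: step probabilities must be >= 0 and sum to 1")
    return out


# ---------------------------------------------------------------------------
# profiles and config
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlayerProfile:
    """Latent behavioural parameters of one simulated gambler."""

    player_id: str
    group: str  # "high" or "low"
    stop_hazard_after_win: float
    stop_hazard_after_loss: float
    stake_change_prob_after_win: float
    stake_change_prob_after_loss: float
    stake_step_win: dict[int, float]   # ladder-step distribution after a win
    stake_step_loss: dict[int, float]  # ladder-step distribution after a loss
    base_stake_level: int
    n_sessions: int
    rt_log_mean: float        # log-ms
    rt_log_sd: float
    post_loss_rt_shift: float  # log-ms; negative = post-loss speeding
    gap_log_mean: float       # start-latency lognormal, log-ms
    gap_log_sd: float
    bankroll_cents: int | None = None  # finite-bankroll mode when set

    def __post_init__(self) -> None:
        for name in (
            "stop_hazard_after_win",
            "stop_hazard_after_loss",
            "stake_change_prob_after_win",
            "stake_change_prob_after_loss",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name}={v} outside [0, 1]")
        if self.rt_log_sd <= 0:
            raise SimConfigError("rt_log_sd must be > 0")
        if self.n_sessions < 1:
            raise SimConfigError("n_sessions must be >= 1")
        if not 0 <= self.base_stake_level <= 9:
            raise SimConfigError("base_stake_level must be a ladder index 0..9")


@dataclass(frozen=True)
class GameSettings:
    """Game-side knobs shared by all simulated players."""

    table: PointTable = DEFAULT_POINT_TABLE
    schedule: StakeSchedule = DEFAULT_STAKE_SCHEDULE
    policy: str = "random"
    later_rt_log_mean: float = math.log(450.0)  # nuisance latencies, columns 2-12
    later_rt_log_sd: float = 0.3


# Per-player parameter fields drawn from per-group distribution specs.
_PROFILE_FIELDS = (
    "stop_hazard_after_win",
    "stop_hazard_after_loss",
    "stake_change_prob_after_win",
    "stake_change_prob_after_loss",
    "base_stake_level",
    "n_sessions",
    "rt_log_mean",
    "rt_log_sd",
    "post_loss_rt_shift",
    "gap_log_mean",
    "gap_log_sd",
)


@dataclass
class SimConfig:
    """Full configuration of a synthetic cohort."""

    n_players: dict[str, int]
    groups: dict[str, dict[str, Any]]  # group -> field -> distribution spec
    seed: int
    game: GameSettings = field(default_factory=GameSettings)
    max_rounds_per_session: int = 1000
    include_column_rts: bool = False

    def __post_init__(self) -> None:
        if set(self.n_players) != {"high", "low"}:
            raise SimConfigError("n_players must have exactly the keys 'high' and 'low'")
        if set(self.groups) != {"high", "low"}:
            raise SimConfigError("groups must have exactly the keys 'high' and 'low'")
        if self.seed is None:
            raise SimConfigError("a seed is mandatory")
        for grp, spec in self.groups.items():
            missing = [f for f in _PROFILE_FIELDS if f not in spec]
            if missing:
                raise SimConfigError(f"group {grp!r} missing parameter spec(s) {missing}")
            for key in ("stake_step_win", "stake_step_loss"):
                if key not in spec:
                    raise SimConfigError(f"group {grp!r} missing {key}")


def default_sim_config(
    seed: int,
    n_high: int = 200,
    n_low: int = 200,
    **overrides: Any,
) -> SimConfig:
    """A cohort configuration with built-in chasing effects.

    Both groups stop more readily after a loss, change stake more often
    after a loss while stepping the stake up mostly after wins, and place
    the first column faster after a loss; the post-loss speeding is
    weaker in the high-involvement group.  High-involvement players play
    more sessions with lower stop hazards and higher stakes.
    """
    groups = {
        "high": {
            "stop_hazard_after_win": {"dist": "normal", "mean": 0.010, "sd": 0.004, "lo": 0.001, "hi": 0.2},
            "stop_hazard_after_loss": {"dist": "normal", "mean": 0.035, "sd": 0.008, "lo": 0.002, "hi": 0.4},
            "stake_change_prob_after_win": {"dist": "normal", "mean": 0.010, "sd": 0.004, "lo": 0.0, "hi": 0.5},
            "stake_change_prob_after_loss": {"dist": "normal", "mean": 0.022, "sd": 0.006, "lo": 0.0, "hi": 0.5},
            "stake_step_win": {1: 0.8, -1: 0.2},
            "stake_step_loss": {1: 0.35, -1: 0.65},
            "base_stake_level": {"dist": "choice", "values": [3, 4, 5, 6], "probs": [0.3, 0.3, 0.25, 0.15]},
            "n_sessions": {"dist": "choice", "values": [6, 8, 10, 12]},
            "rt_log_mean": {"dist": "normal", "mean": math.log(850.0), "sd": 0.12},
            "rt_log_sd": {"dist": "normal", "mean": 0.35, "sd": 0.05, "lo": 0.15},
            "post_loss_rt_shift": {"dist": "normal", "mean": -0.08, "sd": 0.02},
            "gap_log_mean": math.log(2500.0),
            "gap_log_sd": 0.5,
        },
        "low": {
            "stop_hazard_after_win": {"dist": "normal", "mean": 0.012, "sd": 0.004, "lo": 0.001, "hi": 0.2},
            "stop_hazard_after_loss": {"dist": "normal", "mean": 0.032, "sd": 0.008, "lo": 0.002, "hi": 0.4},
            "stake_change_prob_after_win": {"dist": "normal", "mean": 0.012, "sd": 0.004, "lo": 0.0, "hi": 0.5},
            "stake_change_prob_after_loss": {"dist": "normal", "mean": 0.024, "sd": 0.006, "lo": 0.0, "hi": 0.5},
            "stake_step_win": {1: 0.8, -1: 0.2},
            "stake_step_loss": {1: 0.35, -1: 0.65},
            "base_stake_level": {"dist": "choice", "values": [1, 2, 3, 4], "probs": [0.35, 0.35, 0.2, 0.1]},
            "n_sessions": {"dist": "choice", "values": [5, 6, 7, 8]},
            "rt_log_mean": {"dist": "normal", "mean": math.log(1200.0), "sd": 0.12},
            "rt_log_sd": {"dist": "normal", "mean": 0.35, "sd": 0.05, "lo": 0.15},
            "post_loss_rt_shift": {"dist": "normal", "mean": -0.16, "sd": 0.03},
            "gap_log_mean": math.log(3200.0),
            "gap_log_sd": 0.5,
        },
    }
    cfg = dict(n_players={"high": n_high, "low": n_low}, groups=groups, seed=seed)
    cfg.update(overrides)
    return SimConfig(**cfg)


def sample_profiles(config: SimConfig, rng: np.random.Generator) -> list[PlayerProfile]:
    """Draw the per-player latent parameters for both groups."""
    profiles: list[PlayerProfile] = []
    idx = 0
    for grp in ("high", "low"):
        n = config.n_players[grp]
        spec = config.groups[grp]
        draws = {f: _sample_spec(spec[f], rng, n) for f in _PROFILE_FIELDS}
        step_win = _validate_step_dist(spec["stake_step_win"], f"{grp}.stake_step_win")
        step_loss = _validate_step_dist(spec["stake_step_loss"], f"{grp}.stake_step_loss")
        bankroll_spec = spec.get("bankroll_eur")
        bankrolls = (
            _sample_spec(bankroll_spec, rng, n) if bankroll_spec is not None else None
        )
        for i in range(n):
            profiles.append(
                PlayerProfile(
                    player_id=f"p{idx:05d}",
                    group=grp,
                    stop_hazard_after_win=float(draws["stop_hazard_after_win"][i]),
                    stop_hazard_after_loss=float(draws["stop_hazard_after_loss"][i]),
                    stake_change_prob_after_win=float(draws["stake_change_prob_after_win"][i]),
                    stake_change_prob_after_loss=float(draws["stake_change_prob_after_loss"][i]),
                    stake_step_win=step_win,
                    stake_step_loss=step_loss,
                    base_stake_level=int(round(draws["base_stake_level"][i])),
                    n_sessions=int(round(draws["n_sessions"][i])),
                    rt_log_mean=float(draws["rt_log_mean"][i]),
                    rt_log_sd=float(draws["rt_log_sd"][i]),
                    post_loss_rt_shift=float(draws["post_loss_rt_shift"][i]),
                    gap_log_mean=float(draws["gap_log_mean"][i]),
                    gap_log_sd=float(draws["gap_log_sd"][i]),
                    bankroll_cents=(
                        int(round(bankrolls[i] * 100)) if bankrolls is not None else None
                    ),
                )
            )
            idx += 1
    return profiles


class _OutcomePool:
    """Chunked reservoir of simulated round outcomes (random policy)."""

    def __init__(self, table: PointTable, rng: np.random.Generator, chunk: int = 8192):
        self._table = table
        self._rng = rng
        self._chunk = chunk
        self._points = np.empty(0)
        self._bonus = np.empty(0, dtype=bool)
        self._cursor = 0

    def take(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        while len(self._points) - self._cursor < n:
            pts, bon = _game.simulate_points_batch(self._chunk, self._table, self._rng)
            self._points = np.concatenate([self._points[self._cursor:], pts])
            self._bonus = np.concatenate([self._bonus[self._cursor:], bon])
            self._cursor = 0
        sl = slice(self._cursor, self._cursor + n)
        self._cursor += n
        return self._points[sl], self._bonus[sl]


def _step_sampler(steps: Mapping[int, float]):
    vals = np.array(sorted(steps), dtype=np.int64)
    probs = np.array([steps[int(v)] for v in vals], dtype=float)
    return vals, probs


def _session_rows(
    profile: PlayerProfile,
    settings: GameSettings,
    pool: _OutcomePool,
    rng: np.random.Generator,
    max_rounds: int,
) -> dict[str, np.ndarray]:
    """Simulate one session; returns column arrays for its rounds."""
    table, schedule = settings.table, settings.schedule
    levels_cents = np.array(schedule.levels_cents, dtype=np.int64)
    h_w, h_l = profile.stop_hazard_after_win, profile.stop_hazard_after_loss

    # 1. determine session length from outcome-conditional stop hazards
    points = np.empty(0)
    bonus = np.empty(0, dtype=bool)
    stop_u = np.empty(0)
    length = None
    while length is None:
        need = min(max(64, len(points)), max_rounds - len(points))
        if need <= 0:
            length = max_rounds
            break
        pts, bon = pool.take(need)
        points = np.concatenate([points, pts])
        bonus = np.concatenate([bonus, bon])
        stop_u = np.concatenate([stop_u, rng.random(need)])
        wins = points >= table.win_threshold
        stops = stop_u < np.where(wins, h_w, h_l)
        hit = np.flatnonzero(stops)
        if hit.size:
            length = int(hit[0]) + 1
        elif len(points) >= max_rounds:
            length = max_rounds
    points, bonus = points[:length], bonus[:length]
    wins = points >= table.win_threshold

    # 2. stake path (outcome-conditional change probability and step)
    level = np.empty(length, dtype=np.int64)
    level[0] = profile.base_stake_level
    if length > 1:
        change_u = rng.random(length - 1)
        step_u = rng.random(length - 1)
        vals_w, probs_w = _step_sampler(profile.stake_step_win)
        vals_l, probs_l = _step_sampler(profile.stake_step_loss)
        cdf_w, cdf_l = np.cumsum(probs_w), np.cumsum(probs_l)
        for k in range(1, length):
            q = (
                profile.stake_change_prob_after_win
                if wins[k - 1]
                else profile.stake_change_prob_after_loss
            )
            lev = level[k - 1]
            if change_u[k - 1] < q:
                if wins[k - 1]:
                    step = vals_w[np.searchsorted(cdf_w, step_u[k - 1])]
                else:
                    step = vals_l[np.searchsorted(cdf_l, step_u[k - 1])]
                lev = min(max(lev + step, 0), len(levels_cents) - 1)
            level[k] = lev
    stake_cents = levels_cents[level]

    # 3. money
    gross = np.where(
        wins, points * table.prize_rate * (stake_cents / 100.0), 0.0
    )
    win_cents = np.round(gross * 100).astype(np.int64)

    # 4. response times and inter-round gaps
    prev_loss = np.zeros(length, dtype=bool)
    prev_loss[1:] = ~wins[:-1]
    mu = profile.rt_log_mean + np.where(prev_loss, profile.post_loss_rt_shift, 0.0)
    first_rt = np.exp(rng.normal(mu, profile.rt_log_sd))
    gaps = np.exp(rng.normal(profile.gap_log_mean, profile.gap_log_sd, length))
    gaps[0] = np.nan  # session opener: no previous round

    return {
        "stake_cents": stake_cents,
        "win_cents": win_cents,
        "total_points": points,
        "bonus": bonus,
        "first_column_rt_ms": first_rt,
        "start_latency_ms": gaps,
    }


def simulate_player(
    profile: PlayerProfile,
    settings: GameSettings,
    rng: np.random.Generator,
    max_rounds_per_session: int = 1000,
    pool: _OutcomePool | None = None,
    include_column_rts: bool = False,
    keep_points: bool = False,
) -> pd.DataFrame:
    """Round-level tracking rows for one player, all sessions.

    In finite-bankroll mode (``profile.bankroll_cents`` set) the session
    additionally ends as soon as the remaining funds no longer cover the
    next round's stake.
    """
    if pool is None:
        pool = _OutcomePool(settings.table, rng)
    frames = []
    bankroll = profile.bankroll_cents
    for s in range(profile.n_sessions):
        cols = _session_rows(profile, settings, pool, rng, max_rounds_per_session)
        n = len(cols["stake_cents"])
        if bankroll is not None:
            # truncate where cumulative funds run out before the round's stake
            funds = bankroll + np.concatenate(
                [[0], np.cumsum(cols["win_cents"] - cols["stake_cents"])[:-1]]
            )
            ok = funds >= cols["stake_cents"]
            cut = int(np.argmin(ok)) if not ok.all() else n
            if cut == 0:
                break
            cols = {k: v[:cut] for k, v in cols.items()}
            n = cut
            bankroll = int(funds[n - 1] + cols["win_cents"][n - 1] - cols["stake_cents"][n - 1])
        sid = f"{profile.player_id}-s{s + 1:03d}"
        df = pd.DataFrame(
            {
                "player_id": profile.player_id,
                "session_id": sid,
                "round_id": [f"{sid}-r{k + 1:04d}" for k in range(n)],
                "round_index": np.arange(1, n + 1, dtype=np.int64),
                "stake_cents": cols["stake_cents"],
                "win_cents": cols["win_cents"],
                "start_latency_ms": cols["start_latency_ms"],
                "first_column_rt_ms": cols["first_column_rt_ms"],
                "bonus": cols["bonus"],
            }
        )
        if keep_points:
            df["total_points"] = cols["total_points"]
        if include_column_rts:
            later = np.exp(
                rng.normal(settings.later_rt_log_mean, settings.later_rt_log_sd, (n, 11))
            )
            for i in range(11):
                df[f"col_rt_{i + 2}"] = later[:, i]
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def generate_dataset(
    config: SimConfig, keep_points: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the whole cohort.

    Returns the tracking table (one row per round, unique player /
    session / round ids) and the parallel ground-truth table of latent
    profile parameters for parameter-recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    profiles = sample_profiles(config, rng)
    pool = _OutcomePool(config.game.table, rng)
    frames = []
    truth_rows = []
    for prof in profiles:
        df = simulate_player(
            prof,
            config.game,
            rng,
            max_rounds_per_session=config.max_rounds_per_session,
            pool=pool,
            include_column_rts=config.include_column_rts,
            keep_points=keep_points,
        )
        frames.append(df)
        row = asdict(prof)
        row["stake_step_win"] = repr(prof.stake_step_win)
        row["stake_step_loss"] = repr(prof.stake_step_loss)
        row["n_rounds"] = len(df)
        truth_rows.append(row)
    tracking = pd.concat([f for f in frames if len(f)], ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return tracking, truth
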