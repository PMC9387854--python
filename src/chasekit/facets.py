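"""Per-player chasing indicators for the three within-session facets.

Facet 1 (*when to stop*): conditional probabilities of ending a session
after a win / a loss, normalised by the player's overall stop
probability into relative likelihoods of stopping.

Facet 2 (*change in stake*): probability of changing the stake and mean
signed stake change (euro cents), split by the previous round's outcome.

Facet 3 (*speed of play*): mean within-player z-scored first-column RT
split by the previous outcome, after dropping session openers and
over-long RTs.

A round is a win iff its recorded win amount is positive; otherwise it is
a loss (zero-net wins, where the gross prize equals the stake, count as
wins).  Bonus-game rounds are retained everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FacetParams",
    "StopFacetResult",
    "StakeFacetResult",
    "SpeedFacetResult",
    "CohortMetrics",
    "stop_facet",
    "stake_facet",
    "speed_facet",
    "stop_facets",
    "stake_facets",
    "speed_facets",
    "cohort_metrics",
    "play_summary",
]


@dataclass(frozen=True)
class FacetParams:
    """Inclusion filters and exclusions shared by the three facets."""

    min_wins: int = 5           # stop facet: minimum wins and losses
    min_losses: int = 5
    min_after_outcome: int = 5  # stake/speed facets: minimum retained rounds per prior outcome
    rt_max_ms: float = 5000.0   # speed facet: drop rounds with RT strictly above this


@dataclass(frozen=True)
class StopFacetResult:
    n_win: int
    n_loss: int
    p_stop_given_win: float
    p_stop_given_loss: float
    p_stop_overall: float
    rl_win: float
    rl_loss: float
    included: bool


@dataclass(frozen=True)
class StakeFacetResult:
    n_after_win: int
    n_after_loss: int
    p_change_win: float
    p_change_loss: float
    mean_delta_win: float   # euro cents, signed
    mean_delta_loss: float  # euro cents, signed
    included: bool


@dataclass(frozen=True)
class SpeedFacetResult:
    n_after_win: int
    n_after_loss: int
    mean_z_win: float
    mean_z_loss: float
    rt_diff: float  # mean z after loss minus mean z after win
    included: bool


def _ordered(frame: pd.DataFrame) -> pd.DataFrame:
    return frame.sort_values(["player_id", "session_id", "round_index"], kind="stable")


def _with_round_flags(frame: pd.DataFrame) -> pd.DataFrame:
    """Add is_win, is_stop (last round of session) and previous-round context."""
    df = _ordered(frame).copy()
    df["is_win"] = df["win_cents"] > 0
    grp = df.groupby(["player_id", "session_id"], sort=False)
    last_index = grp["round_index"].transform("max")
    df["is_stop"] = df["round_index"] == last_index
    df["prev_win"] = grp["is_win"].shift(1)
    df["prev_stake_cents"] = grp["stake_cents"].shift(1)
    return df


def stop_facets(frame: pd.DataFrame, params: FacetParams = FacetParams()) -> pd.DataFrame:
    """Stop-facet indicators for every player; one row per player.

    ``p_stop_overall`` is computed over *all* rounds of the player, before
    any exclusion.  ``included`` requires at least ``min_wins`` wins and
    ``min_losses`` losses.
    """
    df = _with_round_flags(frame)
    df["stop_and_win"] = df["is_win"] & df["is_stop"]
    g = df.groupby("player_id", sort=True)
    agg = pd.DataFrame(
        {
            "n_win": g["is_win"].sum(),
            "n_round": g.size(),
            "n_stop": g["is_stop"].sum(),
            "n_stop_win": g["stop_and_win"].sum(),
        }
    )
    agg["n_loss"] = agg["n_round"] - agg["n_win"]
    agg["n_stop_loss"] = agg["n_stop"] - agg["n_stop_win"]
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["p_stop_given_win"] = agg["n_stop_win"] / agg["n_win"]
        agg["p_stop_given_loss"] = agg["n_stop_loss"] / agg["n_loss"]
        agg["p_stop_overall"] = agg["n_stop"] / agg["n_round"]
        agg["rl_win"] = agg["p_stop_given_win"] / agg["p_stop_overall"]
        agg["rl_loss"] = agg["p_stop_given_loss"] / agg["p_stop_overall"]
    agg["included"] = (agg["n_win"] >= params.min_wins) & (agg["n_loss"] >= params.min_losses)
    return agg[
        [
            "n_win",
            "n_loss",
            "p_stop_given_win",
            "p_stop_given_loss",
            "p_stop_overall",
            "rl_win",
            "rl_loss",
            "included",
        ]
    ]


def stop_facet(player_frame: pd.DataFrame, params: FacetParams = FacetParams()) -> StopFacetResult:
    """Stop facet for the rounds of a single player."""
    if len(player_frame) == 0:
        raise ValueError("player has no rounds")
    if player_frame["player_id"].nunique() != 1:
        raise ValueError("stop_facet expects the rounds of exactly one player")
    row = stop_facets(player_frame, params).iloc[0]
    return StopFacetResult(
        n_win=int(row["n_win"]),
        n_loss=int(row["n_loss"]),
        p_stop_given_win=float(row["p_stop_given_win"]),
        p_stop_given_loss=float(row["p_stop_given_loss"]),
        p_stop_overall=float(row["p_stop_overall"]),
        rl_win=float(row["rl_win"]),
        rl_loss=float(row["rl_loss"]),
        included=bool(row["included"]),
    )


def stake_facets(frame: pd.DataFrame, params: FacetParams = FacetParams()) -> pd.DataFrame:
    """Stake-facet indicators for every player.

    The first round of each session is excluded (it has no previous
    round).  ``delta`` is current minus previous stake in euro cents; a
    change is any non-zero delta; means are taken over all retained
    rounds of the given prior outcome (zeros included).
    """
    df = _with_round_flags(frame)
    df = df[df["prev_win"].notna()].copy()
    df["delta"] = df["stake_cents"] - df["prev_stake_cents"]
    df["changed"] = df["delta"] != 0
    out = {}
    for label, prev in (("win", True), ("loss", False)):
        sub = df[df["prev_win"] == prev]
        g = sub.groupby("player_id", sort=True)
        out[f"n_after_{label}"] = g.size()
        out[f"p_change_{label}"] = g["changed"].mean()
        out[f"mean_delta_{label}"] = g["delta"].mean()
    agg = pd.DataFrame(out)
    players = pd.Index(frame["player_id"].unique()).sort_values()
    agg = agg.reindex(players)
    for label in ("win", "loss"):
        agg[f"n_after_{label}"] = agg[f"n_after_{label}"].fillna(0).astype(np.int64)
    agg["included"] = (agg["n_after_win"] >= params.min_after_outcome) & (
        agg["n_after_loss"] >= params.min_after_outcome
    )
    agg.index.name = "player_id"
    return agg


def stake_facet(player_frame: pd.DataFrame, params: FacetParams = FacetParams()) -> StakeFacetResult:
    if player_frame["player_id"].nunique() > 1:
        raise ValueError("stake_facet expects the rounds of exactly one player")
    row = stake_facets(player_frame, params).iloc[0]
    return StakeFacetResult(
        n_after_win=int(row["n_after_win"]),
        n_after_loss=int(row["n_after_loss"]),
        p_change_win=float(row["p_change_win"]),
        p_change_loss=float(row["p_change_loss"]),
        mean_delta_win=float(row["mean_delta_win"]),
        mean_delta_loss=float(row["mean_delta_loss"]),
        included=bool(row["included"]),
    )


def speed_facets(frame: pd.DataFrame, params: FacetParams = FacetParams()) -> pd.DataFrame:
    """Speed-facet indicators for every player.

    Session openers and rounds with first-column RT strictly above
    ``rt_max_ms`` are dropped first; the surviving RTs are then z-scored
    within each player (ddof=1).  Players whose retained RTs have zero
    variance are excluded (z undefined).
    """
    df = _with_round_flags(frame)
    df = df[df["prev_win"].notna()]
    df = df[df["first_column_rt_ms"] <= params.rt_max_ms].copy()
    g = df.groupby("player_id", sort=False)["first_column_rt_ms"]
    mu = g.transform("mean")
    sd = g.transform("std")  # ddof=1, matching the reference toolchain
    with np.errstate(invalid="ignore", divide="ignore"):
        df["z"] = (df["first_column_rt_ms"] - mu) / sd
    out = {}
    for label, prev in (("win", True), ("loss", False)):
        sub = df[df["prev_win"] == prev]
        g2 = sub.groupby("player_id", sort=True)
        out[f"n_after_{label}"] = g2.size()
        out[f"mean_z_{label}"] = g2["z"].mean()
    agg = pd.DataFrame(out)
    players = pd.Index(frame["player_id"].unique()).sort_values()
    agg = agg.reindex(players)
    for label in ("win", "loss"):
        agg[f"n_after_{label}"] = agg[f"n_after_{label}"].fillna(0).astype(np.int64)
    agg["rt_diff"] = agg["mean_z_loss"] - agg["mean_z_win"]
    sd_by_player = df.groupby("player_id")["first_column_rt_ms"].std()
    zero_var = sd_by_player.reindex(players).fillna(0.0) == 0
    agg["zero_variance"] = zero_var
    agg["included"] = (
        (agg["n_after_win"] >= params.min_after_outcome)
        & (agg["n_after_loss"] >= params.min_after_outcome)
        & ~zero_var
    )
    agg.index.name = "player_id"
    return agg


def speed_facet(player_frame: pd.DataFrame, params: FacetParams = FacetParams()) -> SpeedFacetResult:
    if player_frame["player_id"].nunique() > 1:
        raise ValueError("speed_facet expects the rounds of exactly one player")
    row = speed_facets(player_frame, params).iloc[0]
    return SpeedFacetResult(
        n_after_win=int(row["n_after_win"]),
        n_after_loss=int(row["n_after_loss"]),
        mean_z_win=float(row["mean_z_win"]),
        mean_z_loss=float(row["mean_z_loss"]),
        rt_diff=float(row["rt_diff"]),
        included=bool(row["included"]),
    )


@dataclass
class CohortMetrics:
    """Per-player facet tables plus included player/round counts per group."""

    stop: pd.DataFrame
    stake: pd.DataFrame
    speed: pd.DataFrame
    counts: pd.DataFrame  # facet x group -> players, rounds


def _facet_round_counts(table: pd.DataFrame, count_cols: list[str]) -> pd.Series:
    return table[count_cols].sum(axis=1)


def cohort_metrics(
    frame: pd.DataFrame,
    groups: pd.Series,
    params: FacetParams = FacetParams(),
) -> CohortMetrics:
    """All three facet tables for a labelled cohort.

    *groups* maps player_id -> ``"high"``/``"low"``; every player in
    *frame* must be labelled.
    """
    players = pd.Index(frame["player_id"].unique())
    unlabeled = players.difference(groups.index)
    if len(unlabeled) > 0:
        raise ValueError(f"players without a group label: {sorted(unlabeled)[:5]}")
    bad = set(groups.loc[players]) - {"high", "low"}
    if bad:
        raise ValueError(f"unknown group labels: {bad}")

    stop = stop_facets(frame, params)
    stake = stake_facets(frame, params)
    speed = speed_facets(frame, params)
    for tbl in (stop, stake, speed):
        tbl.insert(0, "group", groups.reindex(tbl.index))

    rows = []
    for name, tbl, cols in (
        ("stop", stop, ["n_win", "n_loss"]),
        ("stake", stake, ["n_after_win", "n_after_loss"]),
        ("speed", speed, ["n_after_win", "n_after_loss"]),
    ):
        rounds = _facet_round_counts(tbl, cols)
        inc = tbl[tbl["included"]]
        for grp in ("high", "low"):
            sub = inc[inc["group"] == grp]
            sub_rounds = rounds.loc[sub.index]
            rows.append(
                {
                    "facet": name,
                    "group": grp,
                    "players": len(sub),
                    "rounds_mean": float(sub_rounds.mean()) if len(sub) else 0.0,
                    "rounds_sd": float(sub_rounds.std()) if len(sub) > 1 else 0.0,
                    "rounds_min": int(sub_rounds.min()) if len(sub) else 0,
                    "rounds_max": int(sub_rounds.max()) if len(sub) else 0,
                    "rounds_total": int(sub_rounds.sum()) if len(sub) else 0,
                }
            )
    counts = pd.DataFrame(rows)
    return CohortMetrics(stop=stop, stake=stake, speed=speed, counts=counts)


def play_summary(frame: pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """The 12-parameter per-player play-behaviour table.

    Money parameters are in euro.  ``mean_win``/``median_win`` are the net
    win (presented win amount minus the stake) over winning rounds;
    ``mean_loss``/``median_loss`` equal the stake over losing rounds;
    ``total_spent`` is total stakes minus total gross winnings, so a
    positive value means the player lost money overall.
    """
    df = frame.copy()
    df["is_win"] = df["win_cents"] > 0
    df["stake_eur"] = df["stake_cents"] / 100
    df["net_win_eur"] = (df["win_cents"] - df["stake_cents"]) / 100
    g = df.groupby("player_id", sort=True)
    sessions = df.groupby(["player_id", "session_id"], sort=False).size().rename("rounds")
    per_session = sessions.groupby("player_id")
    wins = df[df["is_win"]].groupby("player_id")
    losses = df[~df["is_win"]].groupby("player_id")
    out = pd.DataFrame(
        {
            "n_sessions": per_session.size(),
            "n_rounds": g.size(),
            "mean_rounds_per_session": per_session.mean(),
            "median_rounds_per_session": per_session.median(),
            "mean_stake": g["stake_eur"].mean(),
            "median_stake": g["stake_eur"].median(),
            "p_win": g["is_win"].mean(),
            "mean_win": wins["net_win_eur"].mean(),
            "median_win": wins["net_win_eur"].median(),
            "mean_loss": losses["stake_eur"].mean(),
            "median_loss": losses["stake_eur"].median(),
            "total_spent": g["stake_eur"].sum() - g["win_cents"].sum() / 100,
        }
    )
    if groups is not None:
        out.insert(0, "group", groups.reindex(out.index))
    out.index.name = "player_id"
    return out
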