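"""Structured configuration: one YAML file drives simulation and analysis.

Every analysis artifact embeds the SHA-256 hash of the resolved
configuration plus the seed, so runs are reproducible from the log alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .facets import FacetParams
from .game import BONUS, PointTable, StakeSchedule
from .simulate import GameSettings, SimConfig, default_sim_config

__all__ = ["AnalysisParams", "RunConfig", "load_config", "resolve_config", "config_hash"]


@dataclass(frozen=True)
class AnalysisParams:
    """Filter and test parameters of the analysis pipeline."""

    facets: FacetParams = field(default_factory=FacetParams)
    gap_threshold_ms: float = 600_000.0
    alpha: float = 0.05
    bf_r: float = 0.707

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.bf_r <= 0 or self.gap_threshold_ms < 0 or self.facets.rt_max_ms <= 0:
            raise ValueError("numeric analysis parameters must be positive")


@dataclass
class RunConfig:
    """Everything one CLI run needs."""

    seed: int
    sim: SimConfig
    analysis: AnalysisParams
    raw: dict[str, Any]  # the resolved dict the hash is computed from


def _game_settings(raw: dict[str, Any]) -> GameSettings:
    defaults = GameSettings()
    table_kwargs: dict[str, Any] = {}
    if "faces" in raw:
        table_kwargs["faces"] = tuple(raw["faces"])
        table_kwargs["face_value"] = {str(k): int(v) for k, v in raw["face_value"].items()}
        table_kwargs["bonus_face"] = raw.get("bonus_face", BONUS)
    else:
        table_kwargs["faces"] = defaults.table.faces
        table_kwargs["face_value"] = defaults.table.face_value
        table_kwargs["bonus_face"] = defaults.table.bonus_face
    for key in (
        "win_threshold",
        "slot_bonus_points",
        "multiplier_3slots",
        "multiplier_4slots",
        "prize_rate",
        "bonus_after_multiplier",
        "bonus_game_points",
    ):
        if key in raw:
            table_kwargs[key] = raw[key]
    schedule = (
        StakeSchedule(tuple(float(v) for v in raw["stake_levels"]))
        if "stake_levels" in raw
        else defaults.schedule
    )
    return GameSettings(
        table=PointTable(**table_kwargs),
        schedule=schedule,
        policy=raw.get("policy", defaults.policy),
    )


def resolve_config(raw: dict[str, Any] | None, seed: int | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a raw (YAML-loaded) dict.

    Missing sections fall back to the shipped defaults; an explicit
    *seed* argument overrides the file's seed.
    """
    raw = dict(raw or {})
    eff_seed = seed if seed is not None else raw.get("seed", 0)
    sim_raw = dict(raw.get("simulation") or {})
    game = _game_settings(dict(raw.get("game") or {}))
    n_players = sim_raw.get("n_players", {"high": 200, "low": 200})
    sim = default_sim_config(
        seed=eff_seed,
        n_high=int(n_players["high"]),
        n_low=int(n_players["low"]),
        game=game,
        max_rounds_per_session=int(sim_raw.get("max_rounds_per_session", 1000)),
        include_column_rts=bool(sim_raw.get("include_column_rts", False)),
        **({"groups": sim_raw["groups"]} if "groups" in sim_raw else {}),
    )
    ana_raw = dict(raw.get("analysis") or {})
    facets = FacetParams(
        min_wins=int(ana_raw.get("min_wins", 5)),
        min_losses=int(ana_raw.get("min_losses", 5)),
        min_after_outcome=int(ana_raw.get("min_after_outcome", 5)),
        rt_max_ms=float(ana_raw.get("rt_max_ms", 5000.0)),
    )
    analysis = AnalysisParams(
        facets=facets,
        gap_threshold_ms=float(ana_raw.get("gap_threshold_ms", 600_000.0)),
        alpha=float(ana_raw.get("alpha", 0.05)),
        bf_r=float(ana_raw.get("bf_r", 0.707)),
    )
    resolved = dict(raw)
    resolved["seed"] = eff_seed
    return RunConfig(seed=int(eff_seed), sim=sim, analysis=analysis, raw=resolved)


def load_config(path: str | Path | None, seed: int | None = None) -> RunConfig:
    raw = None
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    return resolve_config(raw, seed=seed)


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 over the resolved configuration and seed."""
    canon = yaml.safe_dump(config.raw, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()
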