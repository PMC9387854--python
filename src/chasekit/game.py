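"""Scoring and simulation of single rounds of the slot-grid dice game.

A round consists of 12 columns of 3 dice each, placed one by one into 4
slots (3 columns per slot, so each slot is a 3x3 grid).  A slot pays the
value of a die face for every completed line (3 rows + 2 diagonals) whose
three faces are identical.  Three identical bonus faces on a line trigger
a bonus mini-game instead of paying points.

The face values, the points-to-money conversion rate, the interior stake
levels and the bonus mini-game payout are *not* part of the public game
description, so they are configurable here and the shipped defaults are
explicitly invented (see :data:`DEFAULT_POINT_TABLE`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "BONUS",
    "PointTable",
    "StakeSchedule",
    "SlotGrid",
    "RoundResult",
    "DEFAULT_POINT_TABLE",
    "DEFAULT_STAKE_SCHEDULE",
    "score_slot",
    "combine_slot_points",
    "score_round",
    "points_to_prize",
    "place_column",
    "simulate_round",
    "simulate_points_batch",
]

#: Distinguished marker for the bonus-play face.
BONUS = "BONUS"

# The 5 scoring lines of a 3x3 slot, as (column, row) index pairs.
# Columns are the placed dice columns; rows/diagonals are the pay lines.
_LINES: tuple[tuple[tuple[int, int], ...], ...] = (
    ((0, 0), (1, 0), (2, 0)),  # top row
    ((0, 1), (1, 1), (2, 1)),  # middle row
    ((0, 2), (1, 2), (2, 2)),  # bottom row
    ((0, 0), (1, 1), (2, 2)),  # main diagonal
    ((0, 2), (1, 1), (2, 0)),  # anti diagonal
)


class GameConfigError(ValueError):
    """Raised for an invalid game configuration."""


@dataclass(frozen=True)
class PointTable:
    """Face set, face values and payout parameters of the game.

    Parameters
    ----------
    faces
        The 10 face identifiers.
    face_value
        Maps every non-bonus face to a non-negative integer point value.
        The bonus face must not appear as a key.
    bonus_face
        The identifier of the bonus-play face, or ``None`` for a table
        without one (useful for degenerate test tables).
    win_threshold
        Minimum total points for a round to count as a win.
    slot_bonus_points
        Extra points when all 9 dice of a slot are identical.
    multiplier_3slots, multiplier_4slots
        Total-points multiplier when exactly 3 / all 4 slots pay points.
    prize_rate
        Euro of gross prize per point per euro staked.
    bonus_after_multiplier
        Whether the all-nine-identical slot bonus is added after the
        3-slot/4-slot multiplier (the shipped default) or before it.
    bonus_game_points
        Points awarded by the (unobserved) bonus mini-game; modelled as a
        fixed draw by default.
    """

    faces: tuple[str, ...]
    face_value: Mapping[str, int]
    bonus_face: str | None = BONUS
    win_threshold: float = 100.0
    slot_bonus_points: float = 200.0
    multiplier_3slots: float = 1.5
    multiplier_4slots: float = 2.0
    prize_rate: float = 0.01
    bonus_after_multiplier: bool = True
    bonus_game_points: float = 150.0

    def __post_init__(self) -> None:
        if len(self.faces) != 10:
            raise GameConfigError(f"expected exactly 10 faces, got {len(self.faces)}")
        if len(set(self.faces)) != 10:
            raise GameConfigError("face identifiers must be unique")
        if self.bonus_face is not None and self.bonus_face not in self.faces:
            raise GameConfigError(f"bonus face {self.bonus_face!r} not among faces")
        for f in self.faces:
            if f == self.bonus_face:
                continue
            v = self.face_value.get(f)
            if v is None:
                raise GameConfigError(f"face {f!r} has no point value")
            if v < 0:
                raise GameConfigError(f"face {f!r} has negative value {v}")

    def value_of(self, face: str) -> float:
        """Point value of a face; the bonus face is worth 0 points."""
        if face == self.bonus_face:
            return 0.0
        return float(self.face_value[face])

    def value_array(self) -> np.ndarray:
        """Per-face values indexed by position in :attr:`faces` (bonus -> 0)."""
        return np.array([self.value_of(f) for f in self.faces], dtype=float)

    def bonus_index(self) -> int:
        """Index of the bonus face in :attr:`faces`, or -1 if absent."""
        if self.bonus_face is None:
            return -1
        return self.faces.index(self.bonus_face)


#: Shipped default table.  The real product's face values are not public;
#: these nine values plus one bonus face are an invented but plausible set.
DEFAULT_POINT_TABLE = PointTable(
    faces=("F5", "F10", "F15", "F20", "F25", "F30", "F40", "F50", "F100", BONUS),
    face_value={
        "F5": 5,
        "F10": 10,
        "F15": 15,
        "F20": 20,
        "F25": 25,
        "F30": 30,
        "F40": 40,
        "F50": 50,
        "F100": 100,
    },
)


@dataclass(frozen=True)
class StakeSchedule:
    """The ordered ladder of stake levels, in euro."""

    levels: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00, 1.50, 2.00, 3.00, 5.00, 10.00, 20.00)

    def __post_init__(self) -> None:
        lv = self.levels
        if len(lv) != 10:
            raise GameConfigError(f"stake ladder must have 10 levels, got {len(lv)}")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise GameConfigError("stake levels must be strictly increasing")
        if abs(lv[0] - 0.25) > 1e-9 or abs(lv[-1] - 20.0) > 1e-9:
            raise GameConfigError("stake ladder must run from 0.25 to 20.00 euro")
        for v in lv:
            if abs(v * 100 - round(v * 100)) > 1e-6:
                raise GameConfigError(f"stake level {v} is not a whole number of cents")

    @property
    def levels_cents(self) -> tuple[int, ...]:
        return tuple(int(round(v * 100)) for v in self.levels)

    def contains(self, stake: float) -> bool:
        return any(abs(stake - v) < 1e-9 for v in self.levels)

    def index_of(self, stake: float) -> int:
        for i, v in enumerate(self.levels):
            if abs(stake - v) < 1e-9:
                return i
        raise GameConfigError(f"stake {stake} is not on the ladder {self.levels}")


DEFAULT_STAKE_SCHEDULE = StakeSchedule()


@dataclass
class SlotGrid:
    """One slot: a 3x3 grid of face ids, filled column by column."""

    columns: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def filled_columns(self) -> int:
        return len(self.columns)

    @property
    def is_full(self) -> bool:
        return len(self.columns) == 3

    def add(self, column: Sequence[str]) -> None:
        if self.is_full:
            raise ValueError("slot already holds 3 columns")
        if len(column) != 3:
            raise ValueError("a column consists of exactly 3 dice")
        self.columns.append(tuple(column))

    def cell(self, col: int, row: int) -> str:
        return self.columns[col][row]


@dataclass(frozen=True)
class RoundResult:
    """Outcome of one fully played round."""

    slot_points: tuple[float, float, float, float]
    total_points: float
    gross_prize: float
    net_win: float
    is_win: bool
    bonus_triggered: bool


def score_slot(grid: SlotGrid, table: PointTable) -> tuple[float, int, bool]:
    """Score one full slot.

    Returns ``(points, bonus_line_count, all_nine_same)`` where *points*
    is the sum, over the 5 lines whose three faces are identical and
    non-bonus, of the repeated face's value.
    """
    if not grid.is_full:
        raise ValueError(f"slot only has {grid.filled_columns} of 3 columns placed")
    points = 0.0
    bonus_lines = 0
    for line in _LINES:
        a, b, c = (grid.cell(col, row) for col, row in line)
        if a == b == c:
            if a == table.bonus_face:
                bonus_lines += 1
            else:
                points += table.value_of(a)
    cells = [grid.cell(col, row) for col in range(3) for row in range(3)]
    return points, bonus_lines, len(set(cells)) == 1


def combine_slot_points(
    slot_points: Sequence[float], any_all_nine: bool, table: PointTable
) -> float:
    """Combine 4 slot totals into round total points.

    The sum is multiplied by 1.5 when exactly 3 slots pay points and by
    2 when all 4 do; the all-nine-identical slot bonus is then added
    (after or before the multiplier per ``table.bonus_after_multiplier``).
    """
    if len(slot_points) != 4:
        raise ValueError("a round has exactly 4 slots")
    total = float(sum(slot_points))
    winning = sum(1 for p in slot_points if p > 0)
    if not table.bonus_after_multiplier and any_all_nine:
        total += table.slot_bonus_points
    if winning == 3:
        total *= table.multiplier_3slots
    elif winning == 4:
        total *= table.multiplier_4slots
    if table.bonus_after_multiplier and any_all_nine:
        total += table.slot_bonus_points
    return total


def score_round(slots: Sequence[SlotGrid], table: PointTable) -> tuple[float, tuple, int]:
    """Score 4 full slots; returns (total_points, slot_points, bonus_line_count)."""
    if len(slots) != 4:
        raise ValueError("a round has exactly 4 slots")
    per_slot = [score_slot(s, table) for s in slots]
    slot_points = tuple(p for p, _, _ in per_slot)
    bonus_lines = sum(b for _, b, _ in per_slot)
    any_nine = any(nine for _, _, nine in per_slot)
    return combine_slot_points(slot_points, any_nine, table), slot_points, bonus_lines


def points_to_prize(
    total_points: float,
    stake: float,
    table: PointTable,
    schedule: StakeSchedule = DEFAULT_STAKE_SCHEDULE,
) -> tuple[float, float, bool]:
    """Convert round points into money.

    Returns ``(gross_prize, net_win, is_win)``; a loss pays gross 0 so the
    loss amount equals the stake.  The stake must sit on the ladder.
    """
    if not schedule.contains(stake):
        raise GameConfigError(f"stake {stake} is not on the ladder {schedule.levels}")
    if total_points >= table.win_threshold:
        gross = total_points * table.prize_rate * stake
        return gross, gross - stake, True
    return 0.0, -stake, False


def _completed_line_points(grid: SlotGrid, table: PointTable) -> float:
    """Points from pay lines that are fully placed (used by greedy placement)."""
    if not grid.is_full:
        return 0.0
    points, _, _ = score_slot(grid, table)
    return points


def place_column(
    policy: Literal["random", "greedy"],
    partial_slots: Sequence[SlotGrid],
    column: Sequence[str],
    table: PointTable,
    rng: np.random.Generator,
) -> int:
    """Choose the slot for the next column.

    ``random`` picks uniformly among non-full slots.  ``greedy`` emulates
    keyboard auto-play: it picks the non-full slot whose immediately
    completed pay lines score the most points, ties broken by the lowest
    slot index.
    """
    open_slots = [i for i, s in enumerate(partial_slots) if not s.is_full]
    if not open_slots:
        raise ValueError("all slots are full")
    if policy == "random":
        return int(open_slots[rng.integers(len(open_slots))])
    if policy != "greedy":
        raise GameConfigError(f"unknown placement policy {policy!r}")
    best, best_pts = open_slots[0], -1.0
    for i in open_slots:
        trial = SlotGrid(columns=list(partial_slots[i].columns))
        trial.add(column)
        pts = _completed_line_points(trial, table)
        if pts > best_pts:
            best, best_pts = i, pts
    return int(best)


def simulate_round(
    stake: float,
    policy: Literal["random", "greedy"],
    table: PointTable,
    rng: np.random.Generator,
    schedule: StakeSchedule = DEFAULT_STAKE_SCHEDULE,
) -> RoundResult:
    """Play one full round: draw 12 columns, place them, score and pay.

    Dice are i.i.d. uniform over the 10 faces.  A triggered bonus
    mini-game adds ``table.bonus_game_points`` before prize conversion.
    """
    if not schedule.contains(stake):
        raise GameConfigError(f"stake {stake} is not on the ladder {schedule.levels}")
    slots = [SlotGrid() for _ in range(4)]
    draws = rng.integers(0, 10, size=(12, 3))
    for k in range(12):
        column = tuple(table.faces[j] for j in draws[k])
        idx = place_column(policy, slots, column, table, rng)
        slots[idx].add(column)
    total, slot_points, bonus_lines = score_round(slots, table)
    bonus_triggered = bonus_lines > 0
    if bonus_triggered:
        total += table.bonus_game_points
    gross, net, win = points_to_prize(total, stake, table, schedule)
    return RoundResult(slot_points, total, gross, net, win, bonus_triggered)


def simulate_points_batch(
    n: int, table: PointTable, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised total points for *n* rounds under the random policy.

    Under uniform random placement each slot ends up holding 3 i.i.d.
    uniform columns, so per-slot contents can be drawn directly.  Returns
    ``(total_points, bonus_triggered)`` with the bonus mini-game payout
    already included in the totals.
    """
    if n == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    values = table.value_array()
    bonus_idx = table.bonus_index()
    # faces[i, slot, col, row]
    faces = rng.integers(0, 10, size=(n, 4, 3, 3), dtype=np.int8)
    slot_points = np.zeros((n, 4))
    bonus_lines = np.zeros((n, 4), dtype=np.int64)
    # 3 rows: identical faces across the 3 columns at the same row
    row_match = (faces[:, :, 0, :] == faces[:, :, 1, :]) & (
        faces[:, :, 1, :] == faces[:, :, 2, :]
    )
    row_face = faces[:, :, 0, :]
    line_faces = [row_face[:, :, r] for r in range(3)]
    line_match = [row_match[:, :, r] for r in range(3)]
    # 2 diagonals
    d1 = (faces[:, :, 0, 0] == faces[:, :, 1, 1]) & (faces[:, :, 1, 1] == faces[:, :, 2, 2])
    d2 = (faces[:, :, 0, 2] == faces[:, :, 1, 1]) & (faces[:, :, 1, 1] == faces[:, :, 2, 0])
    line_faces += [faces[:, :, 0, 0], faces[:, :, 0, 2]]
    line_match += [d1, d2]
    for face, match in zip(line_faces, line_match):
        is_bonus = (face == bonus_idx) if bonus_idx >= 0 else np.zeros(face.shape, dtype=bool)
        slot_points += np.where(match & ~is_bonus, values[face], 0.0)
        bonus_lines += (match & is_bonus).astype(np.int64)
    flat = faces.reshape(n, 4, 9)
    all_nine = (flat == flat[:, :, :1]).all(axis=2)
    any_nine = all_nine.any(axis=1)
    total = slot_points.sum(axis=1)
    winning = (slot_points > 0).sum(axis=1)
    mult = np.where(winning == 3, table.multiplier_3slots, np.where(winning == 4, table.multiplier_4slots, 1.0))
    if table.bonus_after_multiplier:
        total = total * mult + np.where(any_nine, table.slot_bonus_points, 0.0)
    else:
        total = (total + np.where(any_nine, table.slot_bonus_points, 0.0)) * mult
    bonus_triggered = bonus_lines.sum(axis=1) > 0
    total = total + np.where(bonus_triggered, table.bonus_game_points, 0.0)
    return total, bonus_triggered
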