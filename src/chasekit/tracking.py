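"""Reading, validating, writing and resegmenting round-level tracking logs.

The on-disk contract is a UTF-8 CSV with "." decimals and these columns:

========================  =====================================================
column                    meaning
========================  =====================================================
``player_id``             unique player identifier (string)
``session_id``            unique session identifier (string)
``round_id``              unique round identifier (string)
``round_index``           1-based position of the round within its session
``stake``                 stake of the round, euro, at most 2 decimals
``win_amount``            money presented as won, euro; 0 on a loss
``start_latency_ms``      time from the last column of the previous round to
                          starting this round (empty for session openers)
``first_column_rt_ms``    time from round start to placing the first column
``bonus``                 1 if a bonus mini-game occurred, else 0
``col_rt_2``..``col_rt_12``  optional latencies of the later 11 columns
========================  =====================================================

Money is held internally as integer cents (``stake_cents``, ``win_cents``);
values that are not a whole number of cents are rejected at parse time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RoundRecord",
    "TrackingError",
    "ValidationReport",
    "MONEY_COLUMNS",
    "MANDATORY_COLUMNS",
    "read_rounds",
    "read_frame",
    "write_rounds",
    "write_frame",
    "records_to_frame",
    "frame_to_records",
    "validate",
    "resegment_sessions",
]

MONEY_COLUMNS = ("stake", "win_amount")
MANDATORY_COLUMNS = (
    "player_id",
    "session_id",
    "round_id",
    "round_index",
    "stake",
    "win_amount",
    "start_latency_ms",
    "first_column_rt_ms",
    "bonus",
)
OPTIONAL_RT_COLUMNS = tuple(f"col_rt_{i}" for i in range(2, 13))

_MONEY_RE = re.compile(r"^\s*-?\d+(\.\d{1,2})?\s*$")


class TrackingError(ValueError):
    """Raised for malformed tracking files."""


@dataclass(frozen=True)
class RoundRecord:
    """One game round as logged by the operator."""

    player_id: str
    session_id: str
    round_id: str
    round_index: int
    stake_cents: int
    win_cents: int
    start_latency_ms: float  # NaN for the first round of a session
    first_column_rt_ms: float
    bonus: bool
    later_column_rts: tuple[float, ...] | None = None


@dataclass
class ValidationReport:
    """Accumulated invariant violations; empty means clean data."""

    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __len__(self) -> int:
        return len(self.issues)


def _parse_money_cents(series: pd.Series, column: str) -> pd.Series:
    """Parse a euro column given as strings into exact integer cents."""
    text = series.astype(str).str.strip()
    bad = ~text.map(lambda s: bool(_MONEY_RE.match(s)))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TrackingError(
            f"column {column!r}, row {row}: value {text.iloc[row]!r} "
            "is not representable in whole euro cents"
        )
    return (text.astype(float) * 100).round().astype(np.int64)


def read_frame(path: str | Path) -> pd.DataFrame:
    """Read a tracking CSV into the canonical internal frame.

    Money columns become integer cents; missing start latencies become NaN.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={
            "player_id": str,
            "session_id": str,
            "round_id": str,
            "stake": str,
            "win_amount": str,
        },
    )
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise TrackingError(f"{path}: missing mandatory column(s) {missing}")
    out = pd.DataFrame(
        {
            "player_id": df["player_id"],
            "session_id": df["session_id"],
            "round_id": df["round_id"],
            "round_index": pd.to_numeric(df["round_index"], errors="raise").astype(np.int64),
            "stake_cents": _parse_money_cents(df["stake"], "stake"),
            "win_cents": _parse_money_cents(df["win_amount"], "win_amount"),
            "start_latency_ms": pd.to_numeric(df["start_latency_ms"], errors="raise"),
            "first_column_rt_ms": pd.to_numeric(df["first_column_rt_ms"], errors="raise"),
            "bonus": pd.to_numeric(df["bonus"], errors="raise").astype(bool),
        }
    )
    for c in OPTIONAL_RT_COLUMNS:
        if c in df.columns:
            out[c] = pd.to_numeric(df[c], errors="raise")
    dup = out.duplicated(subset=["player_id", "session_id", "round_index"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        key = out.loc[row, ["player_id", "session_id", "round_index"]].tolist()
        raise TrackingError(f"{path}: duplicate (player, session, round_index) key {key} at row {row}")
    return out


def write_frame(frame: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical internal frame as a tracking CSV."""
    out = pd.DataFrame(
        {
            "player_id": frame["player_id"],
            "session_id": frame["session_id"],
            "round_id": frame["round_id"],
            "round_index": frame["round_index"],
            "stake": (frame["stake_cents"] / 100).map(lambda v: f"{v:.2f}"),
            "win_amount": (frame["win_cents"] / 100).map(lambda v: f"{v:.2f}"),
            "start_latency_ms": frame["start_latency_ms"],
            "first_column_rt_ms": frame["first_column_rt_ms"],
            "bonus": frame["bonus"].astype(int),
        }
    )
    for c in OPTIONAL_RT_COLUMNS:
        if c in frame.columns:
            out[c] = frame[c]
    out.to_csv(path, index=False)


def read_rounds(path: str | Path) -> list[RoundRecord]:
    """Read a tracking CSV as a list of :class:`RoundRecord`."""
    return frame_to_records(read_frame(path))


def write_rounds(records: list[RoundRecord], path: str | Path) -> None:
    write_frame(records_to_frame(records), path)


def records_to_frame(records: list[RoundRecord]) -> pd.DataFrame:
    cols = {
        "player_id": [r.player_id for r in records],
        "session_id": [r.session_id for r in records],
        "round_id": [r.round_id for r in records],
        "round_index": np.array([r.round_index for r in records], dtype=np.int64),
        "stake_cents": np.array([r.stake_cents for r in records], dtype=np.int64),
        "win_cents": np.array([r.win_cents for r in records], dtype=np.int64),
        "start_latency_ms": np.array([r.start_latency_ms for r in records], dtype=float),
        "first_column_rt_ms": np.array([r.first_column_rt_ms for r in records], dtype=float),
        "bonus": np.array([r.bonus for r in records], dtype=bool),
    }
    frame = pd.DataFrame(cols)
    if records and records[0].later_column_rts is not None:
        rts = np.array([r.later_column_rts for r in records], dtype=float)
        for i, c in enumerate(OPTIONAL_RT_COLUMNS):
            frame[c] = rts[:, i]
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[RoundRecord]:
    has_rts = all(c in frame.columns for c in OPTIONAL_RT_COLUMNS)
    records = []
    for row in frame.itertuples(index=False):
        later = (
            tuple(getattr(row, c) for c in OPTIONAL_RT_COLUMNS) if has_rts else None
        )
        records.append(
            RoundRecord(
                player_id=row.player_id,
                session_id=row.session_id,
                round_id=row.round_id,
                round_index=int(row.round_index),
                stake_cents=int(row.stake_cents),
                win_cents=int(row.win_cents),
                start_latency_ms=float(row.start_latency_ms),
                first_column_rt_ms=float(row.first_column_rt_ms),
                bonus=bool(row.bonus),
                later_column_rts=later,
            )
        )
    return records


def validate(frame: pd.DataFrame) -> ValidationReport:
    """Check every record-level invariant; reports rather than raises."""
    report = ValidationReport()

    def flag(mask: np.ndarray | pd.Series, message: str) -> None:
        mask = np.asarray(mask)
        for row in np.flatnonzero(mask)[:50]:
            report.issues.append(f"row {row}: {message}")
        extra = int(mask.sum()) - min(int(mask.sum()), 50)
        if extra > 0:
            report.issues.append(f"... and {extra} more rows: {message}")

    flag(frame["stake_cents"] <= 0, "stake must be positive")
    flag(frame["win_cents"] < 0, "win amount must be non-negative")
    flag(frame["first_column_rt_ms"] < 0, "negative first-column RT")
    flag(frame["start_latency_ms"] < 0, "negative start latency")
    flag(frame["round_index"] < 1, "round index must be 1-based")
    dup = frame.duplicated(subset=["player_id", "session_id", "round_index"])
    flag(dup, "duplicate (player, session, round_index)")
    # round order within session strictly increasing in file order
    grp = frame.groupby(["player_id", "session_id"], sort=False)["round_index"]
    nonmono = grp.transform(lambda s: s.diff().fillna(1) <= 0)
    flag(nonmono, "round_index not strictly increasing within session")
    return report


def resegment_sessions(
    frame: pd.DataFrame, gap_threshold_ms: float = 600_000.0
) -> tuple[pd.DataFrame, ValidationReport]:
    """Split sessions at response breaks longer than *gap_threshold_ms*.

    A round whose ``start_latency_ms`` is strictly greater than the
    threshold starts a new session.  Operator session boundaries are only
    split, never merged; session openers (no meaningful latency) never
    split.  Rounds with a missing latency cannot be assessed and are
    flagged in the returned report (treated as non-breaks).
    """
    frame = frame.sort_values(["player_id", "session_id", "round_index"], kind="stable")
    report = ValidationReport()
    not_first = frame["round_index"].to_numpy() > 1
    latency = frame["start_latency_ms"].to_numpy(dtype=float)
    missing = np.isnan(latency) & not_first
    for row in np.flatnonzero(missing)[:50]:
        report.issues.append(
            f"row {row}: missing start_latency_ms, cannot assess break; kept in session"
        )
    breaks = not_first & ~missing & (latency > gap_threshold_ms)
    # split counter within each operator session
    part = (
        pd.Series(breaks, index=frame.index)
        .groupby([frame["player_id"], frame["session_id"]], sort=False)
        .cumsum()
        .astype(int)
    )
    out = frame.copy()
    sid = frame["session_id"].to_numpy(dtype=object)
    part_arr = part.to_numpy()
    split_sessions = (
        part.groupby([frame["player_id"], frame["session_id"]], sort=False).transform("max") > 0
    ).to_numpy()
    new_sid = np.where(
        split_sessions,
        np.array([f"{s}.{k + 1}" for s, k in zip(sid, part_arr)], dtype=object),
        sid,
    )
    out["session_id"] = new_sid
    out["round_index"] = (
        out.groupby(["player_id", "session_id"], sort=False).cumcount() + 1
    ).astype(np.int64)
    return out.reset_index(drop=True), report
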