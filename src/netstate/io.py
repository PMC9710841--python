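"""Reading, validating and work-week splitting of the two raw sensing logs.

Two CSV logs drive the pipeline:

* an *interaction log* of directed badge detections, one row per event,
  with columns ``timestamp,logger_id,detected_id`` (the participant whose
  detector produced the record, and the participant detected);
* an *EMA log* of momentary personality-state self-reports, with columns
  ``timestamp,participant_id,extra,agree,consc,stabl,open`` where the five
  trait scores live on a 1-7 Likert scale in half-point increments (each
  score is the mean of two integer item responses).

Both dialects are configurable through a column map so deposits with other
header names can be read without code changes.  All downstream containers
are plain :class:`pandas.DataFrame` objects with these canonical columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical short names of the five personality-state dimensions
#: (extraversion, agreeableness, conscientiousness, emotional stability,
#: openness to experience), in fixed column order.
TRAITS: tuple[str, ...] = ("extra", "agree", "consc", "stabl", "open")

INTERACTION_COLUMNS: tuple[str, ...] = ("timestamp", "logger_id", "detected_id")
EMA_COLUMNS: tuple[str, ...] = ("timestamp", "participant_id") + TRAITS

SCORE_MIN = 1.0
SCORE_MAX = 7.0


@dataclass(frozen=True, order=True)
class WorkWeek:
    """One Monday-to-Friday observation week.

    ``start_date`` must be a Monday and ``end_date`` the following Friday;
    date membership is inclusive on both ends (weekends are dropped before
    weeks are assigned, so the convention only matters for weekdays).
    """

    index: int
    start_date: date
    end_date: date

    def __post_init__(self) -> None:
        if self.start_date.weekday() != 0:
            raise ValueError(f"week {self.index} start {self.start_date} is not a Monday")
        if self.end_date - self.start_date != timedelta(days=4):
            raise ValueError(f"week {self.index} does not span Monday-Friday")

    def contains(self, when: date | datetime) -> bool:
        d = when.date() if isinstance(when, datetime) else when
        return self.start_date <= d <= self.end_date


def work_weeks(start_monday: date, n_weeks: int) -> list[WorkWeek]:
    """Build ``n_weeks`` consecutive Monday-Friday weeks from a start Monday."""
    if start_monday.weekday() != 0:
        raise ValueError(f"{start_monday} is not a Monday")
    return [
        WorkWeek(i + 1, start_monday + timedelta(weeks=i), start_monday + timedelta(weeks=i, days=4))
        for i in range(n_weeks)
    ]


def _read_csv(path: str | Path, column_map: Mapping[str, str] | None, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"log file not found: {path}")
    df = pd.read_csv(path, skipinitialspace=True)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df[list(required)].copy()


def _parse_timestamps(df: pd.DataFrame) -> pd.DataFrame:
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    bad = ts.isna().sum()
    if bad:
        logger.warning("dropped %d rows with unparseable timestamps", bad)
    df = df.loc[ts.notna()].copy()
    df["timestamp"] = ts.loc[ts.notna()]
    return df


def _window_filter(df: pd.DataFrame, window: tuple[date, date] | None) -> pd.DataFrame:
    if window is None:
        return df
    lo, hi = window
    dates = df["timestamp"].dt.date
    keep = (dates >= lo) & (dates <= hi)
    if (~keep).any():
        logger.warning("dropped %d rows outside the study window", int((~keep).sum()))
    return df.loc[keep]


def parse_interaction_log(
    path: str | Path,
    window: tuple[date, date] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Parse a directed badge-detection log.

    Drops malformed rows, self-detections (``logger_id == detected_id``),
    Saturday/Sunday records and records outside ``window``, logging a count
    for each; the result is sorted by timestamp.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` when
    no valid rows survive.
    """
    df = _read_csv(path, column_map, INTERACTION_COLUMNS)
    n_raw = len(df)
    df = _parse_timestamps(df)
    df = df.dropna(subset=["logger_id", "detected_id"])

    self_loops = df["logger_id"] == df["detected_id"]
    if self_loops.any():
        logger.warning("dropped %d self-detection rows", int(self_loops.sum()))
    df = df.loc[~self_loops]

    weekend = df["timestamp"].dt.weekday >= 5
    if weekend.any():
        logger.warning("dropped %d weekend rows", int(weekend.sum()))
    df = df.loc[~weekend]

    df = _window_filter(df, window)
    if df.empty:
        raise ValueError(f"{path}: no valid interaction rows (of {n_raw} read)")
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def parse_ema_log(
    path: str | Path,
    window: tuple[date, date] | None = None,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Parse the EMA self-report log (five trait scores per prompt).

    Rows with any score outside [1, 7] or unparseable are dropped with a
    warning.  Output is sorted by (participant, timestamp); ties keep file
    order (stable sort), which downstream RMSSD computation relies on.
    """
    df = _read_csv(path, column_map, EMA_COLUMNS)
    n_raw = len(df)
    df = _parse_timestamps(df)
    df = df.dropna(subset=["participant_id"])

    for trait in TRAITS:
        df[trait] = pd.to_numeric(df[trait], errors="coerce")
    scores = df[list(TRAITS)]
    ok = scores.notna().all(axis=1) & (scores >= SCORE_MIN).all(axis=1) & (scores <= SCORE_MAX).all(axis=1)
    if (~ok).any():
        logger.warning("dropped %d EMA rows with missing/out-of-range scores", int((~ok).sum()))
    df = df.loc[ok]

    df = _window_filter(df, window)
    if df.empty:
        raise ValueError(f"{path}: no valid EMA rows (of {n_raw} read)")
    return df.sort_values(["participant_id", "timestamp"], kind="stable").reset_index(drop=True)


def split_work_weeks(records: pd.DataFrame, weeks: Sequence[WorkWeek]) -> dict[int, pd.DataFrame]:
    """Partition parsed records into per-week groups keyed by week index.

    Every retained record lands in exactly one group (weeks are disjoint);
    records outside all weeks are dropped with a warning.  Empty weeks map
    to empty frames so the group count always equals ``len(weeks)``.
    """
    groups: dict[int, pd.DataFrame] = {}
    if records.empty:
        dates = pd.Series([], dtype=object)
    else:
        dates = records["timestamp"].dt.date
    assigned = pd.Series(False, index=records.index)
    for wk in weeks:
        mask = (dates >= wk.start_date) & (dates <= wk.end_date) if len(records) else pd.Series([], dtype=bool)
        groups[wk.index] = records.loc[mask].reset_index(drop=True)
        assigned |= mask
    n_lost = int((~assigned).sum()) if len(records) else 0
    if n_lost:
        logger.warning("dropped %d records outside all configured weeks", n_lost)
    return groups


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tabular artifact as headered CSV (canonical on-disk form)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"artifact not found: {path}")
    return pd.read_csv(path)
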