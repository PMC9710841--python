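"""Within-week personality-state variability outcomes (RMSSD).

For each participant, week and trait, the ordered EMA responses
x_1 .. x_N give the root mean square of successive differences

    RMSSD = sqrt( Σ_{i=1}^{N-1} (x_i − x_{i+1})² / (N − 1) )

— the standard moment-to-moment variability statistic of the EMA
literature.  A week needs at least two responses (one difference);
otherwise the person-week outcome is missing, never silently zero.
On the 1-7 response scale RMSSD is bounded by 6.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io import TRAITS


def rmssd(series: Sequence[float] | np.ndarray) -> float:
    """RMSSD of one chronologically ordered series; NaN when N < 2."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(np.sqrt(np.mean(np.diff(x) ** 2)))


def build_outcome_table(weekly_ema: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Per (participant, week) RMSSD for the five traits.

    Responses are ordered by timestamp within each participant-week
    (timestamp ties keep input order, which the parser's stable sort
    established).  Person-weeks with fewer than two responses produce no
    row.  All responses of a week form a single series; overnight gaps are
    treated like any other successive pair.
    """
    rows = []
    for week, ema in sorted(weekly_ema.items()):
        if ema.empty:
            continue
        ordered = ema.sort_values("timestamp", kind="stable")
        for pid, grp in ordered.groupby("participant_id", sort=True):
            if len(grp) < 2:
                continue
            row = {"participant_id": pid, "week": week}
            for trait in TRAITS:
                row[trait] = rmssd(grp[trait].to_numpy())
            rows.append(row)
    return pd.DataFrame(rows, columns=["participant_id", "week", *TRAITS])


def summarize_outcomes(table: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary per week and trait: median, min, max across
    participants (median of an even count uses midpoint interpolation)."""
    if table.empty:
        raise ValueError("empty outcome table")
    rows = []
    for week, grp in table.groupby("week", sort=True):
        for trait in TRAITS:
            vals = grp[trait].dropna()
            rows.append(
                {
                    "week": week,
                    "trait": trait,
                    "median": float(vals.median()),
                    "min": float(vals.min()),
                    "max": float(vals.max()),
                }
            )
    return pd.DataFrame(rows)
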