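"""The three canonical report tables, as CSV.

1. Weekly outcome summary — per week and trait the cohort median
   [min, max] RMSSD.
2. Participant performance — per participant the min/max/avg R² and
   normalized RMSE across the five trait models plus the consistently-
   informative flag, ranked by minimum R² (desc) then average normalized
   RMSE (asc).
3. Importance profile — per feature the five scaled importances, their
   cross-trait average and rank, sorted by descending average.

Every cell is recomputable from the upstream CSV artifacts alone; these
functions only arrange, sort and format.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .io import TRAITS, write_table


def render_outcome_summary(summary: pd.DataFrame) -> pd.DataFrame:
    """Wide weekly summary: one row per week, one ``median [min, max]``
    column per trait."""
    wide = summary.pivot(index="week", columns="trait", values=["median", "min", "max"])
    rows = []
    for week in wide.index:
        row = {"week": int(week)}
        for trait in TRAITS:
            med = wide.loc[week, ("median", trait)]
            lo = wide.loc[week, ("min", trait)]
            hi = wide.loc[week, ("max", trait)]
            row[trait] = f"{med:.2f} [{lo:.2f}, {hi:.2f}]"
        rows.append(row)
    return pd.DataFrame(rows)


def render_participant_performance(participant_table: pd.DataFrame) -> pd.DataFrame:
    """Already-sorted per-participant table, rounded for presentation."""
    out = participant_table.copy()
    for col in ("r2_min", "r2_max", "r2_avg", "nrmse_min", "nrmse_max", "nrmse_avg"):
        out[col] = out[col].round(2)
    return out


def render_importance_profile(profile: pd.DataFrame) -> pd.DataFrame:
    out = profile.copy()
    for col in out.columns:
        if col not in ("feature", "rank"):
            out[col] = out[col].round(2)
    return out


def render_reports(
    outcome_summary: pd.DataFrame,
    participant_table: pd.DataFrame,
    importance_profile: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    out = Path(out_dir)
    paths = {
        "weekly_outcomes": out / "report_weekly_outcomes.csv",
        "participant_performance": out / "report_participant_performance.csv",
        "importance_profile": out / "report_importance_profile.csv",
    }
    write_table(render_outcome_summary(outcome_summary), paths["weekly_outcomes"])
    write_table(render_participant_performance(participant_table), paths["participant_performance"])
    write_table(render_importance_profile(importance_profile), paths["importance_profile"])
    return paths
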