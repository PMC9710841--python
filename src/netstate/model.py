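"""Leave-one-subject-out gradient-boosted modeling of personality-state
change from network features.

The central object is :class:`StateChangeModel`: person-week rows of the
26 network features (plus the week index) predicting one trait's weekly
RMSSD.  ``fit()`` runs leave-one-subject-out (LOSO) cross-validation —
every fold holds out *all* rows of one participant (1 to n_weeks rows)
and trains on everyone else — with hyperparameters tuned per fold by
participant-grouped inner cross-validation over a small grid, and returns
a :class:`StateChangeResults` carrying per-fold metrics, cohort summaries
and permutation-importance hooks.

Fold metrics follow the conventions of the original R tooling this kind
of analysis is usually run with: R² is the squared Pearson correlation
between observed and predicted values (undefined below three rows or
under zero variance on either side; ``r2_method="ss"`` switches to
1 − SSres/SStot), and RMSE is additionally reported normalized by the
observed RMSSD range pooled across traits.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import GroupKFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBRegressor

from .features import MATRIX_COLUMNS
from .io import TRAITS

#: Default tuning grid: three levels for the tree-count and depth, one
#: sensible value elsewhere (nine candidates).  Fully overridable.
DEFAULT_GRID: dict[str, tuple] = {
    "nrounds": (50, 100, 150),
    "max_depth": (1, 2, 3),
    "eta": (0.3,),
    "gamma": (0.0,),
    "colsample_bytree": (0.8,),
    "min_child_weight": (1.0,),
    "subsample": (0.75,),
}

#: Single-candidate grid for large simulation sweeps where tuning cost
#: dominates; a one-point grid skips the inner loop entirely.
REDUCED_GRID: dict[str, tuple] = {
    "nrounds": (60,),
    "max_depth": (3,),
    "eta": (0.3,),
    "gamma": (0.0,),
    "colsample_bytree": (0.8,),
    "min_child_weight": (1.0,),
    "subsample": (0.8,),
}

_XGB_NAMES = {"nrounds": "n_estimators", "eta": "learning_rate"}

INFORMATIVE_R2_MIN = 0.05
INFORMATIVE_NRMSE_MAX = 0.25


@dataclass(frozen=True)
class ModelConfig:
    """Knobs of the LOSO pipeline (all defaulted; see module docstring)."""

    grid: Mapping[str, tuple] = field(default_factory=lambda: dict(DEFAULT_GRID))
    seed: int = 2012
    inner_folds: int = 5
    r2_method: Literal["pearson", "ss"] = "pearson"
    norm_range: float | None = None  # pooled observed outcome range; inferred when None


def expand_grid(grid: Mapping[str, Sequence]) -> list[dict[str, float]]:
    """Cartesian product of the grid in deterministic key order."""
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def _make_regressor(params: Mapping[str, float], seed: int) -> XGBRegressor:
    kwargs = {_XGB_NAMES.get(k, k): v for k, v in params.items()}
    kwargs["n_estimators"] = int(kwargs["n_estimators"])
    kwargs["max_depth"] = int(kwargs["max_depth"])
    return XGBRegressor(
        objective="reg:squarederror",
        n_jobs=1,
        random_state=int(seed),
        tree_method="hist",
        verbosity=0,
        **kwargs,
    )


def fold_seed(base_seed: int, participant_id) -> int:
    """Stable per-fold seed independent of fold execution order."""
    return int((base_seed + zlib.crc32(str(participant_id).encode())) % (2**31 - 1))


def join_rows(features: pd.DataFrame, outcomes: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Inner-join the predictor matrix with one trait's outcomes on
    (participant_id, week); rows lacking either side are dropped."""
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    out = outcomes[["participant_id", "week", trait]].dropna(subset=[trait])
    joined = features.merge(out, on=["participant_id", "week"], how="inner")
    if joined.empty:
        raise ValueError("feature matrix and outcome table share no (participant, week) keys")
    return joined.sort_values(["participant_id", "week"], kind="stable").reset_index(drop=True)


def loso_folds(table: pd.DataFrame) -> list[tuple[object, np.ndarray, np.ndarray]]:
    """One fold per participant: (held_out_id, train positions, test
    positions).  Test sides partition the table."""
    pids = sorted(table["participant_id"].unique(), key=repr)
    if len(pids) < 2:
        raise ValueError("LOSO needs at least two participants")
    folds = []
    pid_col = table["participant_id"].to_numpy()
    for pid in pids:
        test = np.flatnonzero(pid_col == pid)
        train = np.flatnonzero(pid_col != pid)
        folds.append((pid, train, test))
    return folds


def tune_and_fit(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    grid: Mapping[str, Sequence],
    seed: int,
    inner_folds: int = 5,
) -> tuple[XGBRegressor, dict[str, float]]:
    """Grid-tune on participant-grouped inner CV, then refit on all rows.

    The winning candidate minimizes mean inner-fold RMSE; ties resolve to
    the first candidate in grid order.  A one-point grid skips the inner
    loop.  Grouping by participant keeps a subject's rows on one side of
    every inner split, so tuning cannot leak within-person structure.
    """
    candidates = expand_grid(grid)
    if not candidates:
        raise ValueError("empty hyperparameter grid")
    if len(candidates) == 1:
        best = candidates[0]
    else:
        n_groups = len(np.unique(groups))
        splitter = GroupKFold(n_splits=min(inner_folds, n_groups))
        splits = list(splitter.split(X, y, groups))
        best, best_rmse = None, np.inf
        for params in candidates:
            rmses = []
            for tr, va in splits:
                reg = _make_regressor(params, seed)
                reg.fit(X.iloc[tr], y[tr])
                pred = reg.predict(X.iloc[va])
                rmses.append(float(np.sqrt(np.mean((y[va] - pred) ** 2))))
            mean_rmse = float(np.mean(rmses))
            if mean_rmse < best_rmse - 1e-12:
                best, best_rmse = params, mean_rmse
        assert best is not None
    final = _make_regressor(best, seed)
    final.fit(X, y)
    return final, dict(best)


def _fold_r2(observed: np.ndarray, predicted: np.ndarray, method: str) -> float:
    if method == "ss":
        sst = float(np.sum((observed - observed.mean()) ** 2))
        if len(observed) < 3 or sst == 0:
            return float("nan")
        return 1.0 - float(np.sum((observed - predicted) ** 2)) / sst
    if len(observed) < 3 or np.std(observed) == 0 or np.std(predicted) == 0:
        return float("nan")
    return float(np.corrcoef(observed, predicted)[0, 1] ** 2)


@dataclass
class FoldResult:
    """Held-out metrics for one participant's LOSO fold."""

    held_out_id: object
    observed: np.ndarray
    predicted: np.ndarray
    r2: float
    rmse: float
    rmse_normalized: float
    params: dict[str, float]
    seed: int
    model: XGBRegressor | None = None
    train_index: np.ndarray | None = None


def evaluate_fold(
    model,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    norm_range: float,
    r2_method: str = "pearson",
) -> tuple[float, float, float, np.ndarray]:
    """Fold metrics: (r2, rmse, rmse / outcome range, predictions)."""
    pred = np.asarray(model.predict(X_test), dtype=float)
    rmse = float(np.sqrt(np.mean((y_test - pred) ** 2)))
    r2 = _fold_r2(y_test, pred, r2_method)
    nrmse = rmse / norm_range if norm_range > 0 else float("nan")
    return r2, rmse, nrmse, pred


class StateChangeModel:
    """Gradient-boosted LOSO model of one trait's weekly RMSSD.

    Parameters
    ----------
    data : DataFrame
        Modeling table with ``participant_id``, the 27 predictor columns
        (26 network features + ``week``) and the outcome column.
    trait : str
        Outcome column name (one of :data:`netstate.io.TRAITS`).
    config : ModelConfig, optional
    """

    def __init__(self, data: pd.DataFrame, trait: str, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        missing = [c for c in (*MATRIX_COLUMNS, trait, "participant_id") if c not in data.columns]
        if missing:
            raise ValueError(f"modeling table missing columns {missing}")
        self.data = data.reset_index(drop=True)
        self.trait = trait
        self.feature_columns = list(MATRIX_COLUMNS)  # 26 features + week

    @classmethod
    def from_tables(
        cls,
        features: pd.DataFrame,
        outcomes: pd.DataFrame,
        trait: str,
        config: ModelConfig | None = None,
    ) -> "StateChangeModel":
        """Build from a feature matrix and an outcome table (inner join)."""
        return cls(join_rows(features, outcomes, trait), trait, config=config)

    @property
    def exog(self) -> pd.DataFrame:
        return self.data[self.feature_columns]

    @property
    def endog(self) -> np.ndarray:
        return self.data[self.trait].to_numpy(dtype=float)

    def _norm_range(self) -> float:
        if self.config.norm_range is not None:
            return self.config.norm_range
        y = self.endog
        return float(y.max() - y.min())

    def fit(self, keep_models: bool = True) -> "StateChangeResults":
        """Run the full LOSO loop; deterministic for a fixed config."""
        X, y = self.exog, self.endog
        groups = self.data["participant_id"].to_numpy()
        norm_range = self._norm_range()
        fold_results: list[FoldResult] = []
        for pid, train, test in loso_folds(self.data):
            seed = fold_seed(self.config.seed, pid)
            model, params = tune_and_fit(
                X.iloc[train], y[train], groups[train], self.config.grid, seed, self.config.inner_folds
            )
            r2, rmse, nrmse, pred = evaluate_fold(model, X.iloc[test], y[test], norm_range, self.config.r2_method)
            fold_results.append(
                FoldResult(
                    held_out_id=pid,
                    observed=y[test],
                    predicted=pred,
                    r2=r2,
                    rmse=rmse,
                    rmse_normalized=nrmse,
                    params=params,
                    seed=seed,
                    model=model if keep_models else None,
                    train_index=train if keep_models else None,
                )
            )
        return StateChangeResults(self, fold_results, norm_range)


class StateChangeResults:
    """Fold-level and cohort-level results of one trait's LOSO run."""

    def __init__(self, model: StateChangeModel, fold_results: list[FoldResult], norm_range: float):
        self.model = model
        self.trait = model.trait
        self.fold_results = fold_results
        self.norm_range = norm_range

    @property
    def r2_mean(self) -> float:
        """Cohort-average R² over folds where it is defined."""
        vals = [f.r2 for f in self.fold_results if np.isfinite(f.r2)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def r2_pooled(self) -> float:
        """Cross-validated R² over all held-out predictions pooled across
        folds (under the configured convention).

        Unlike the fold-average, which at 6-row folds carries a chance
        floor of roughly 1/(n−1) ≈ 0.2 under the squared-Pearson
        convention, the pooled statistic is ≈ 0 when predictors carry no
        signal, which makes it the right quantity for signal-vs-null
        comparisons.
        """
        obs = np.concatenate([f.observed for f in self.fold_results])
        pred = np.concatenate([f.predicted for f in self.fold_results])
        if self.model.config.r2_method == "ss":
            sst = float(np.sum((obs - obs.mean()) ** 2))
            return 1.0 - float(np.sum((obs - pred) ** 2)) / sst if sst > 0 else float("nan")
        if np.std(obs) == 0 or np.std(pred) == 0:
            return float("nan")
        return float(np.corrcoef(obs, pred)[0, 1] ** 2)

    @property
    def rmse_mean(self) -> float:
        return float(np.mean([f.rmse for f in self.fold_results]))

    @property
    def rmse_normalized_mean(self) -> float:
        return float(np.mean([f.rmse_normalized for f in self.fold_results]))

    def fold_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [f.held_out_id for f in self.fold_results],
                "n_rows": [len(f.observed) for f in self.fold_results],
                "r2": [f.r2 for f in self.fold_results],
                "rmse": [f.rmse for f in self.fold_results],
                "rmse_normalized": [f.rmse_normalized for f in self.fold_results],
            }
        )

    def predictions(self) -> pd.DataFrame:
        frames = []
        for f in self.fold_results:
            frames.append(
                pd.DataFrame(
                    {"participant_id": f.held_out_id, "observed": f.observed, "predicted": f.predicted}
                )
            )
        return pd.concat(frames, ignore_index=True)

    def importance(self, n_repeats: int = 10, scope: Literal["folds", "pooled"] = "folds") -> pd.Series:
        """Raw permutation importances (mean RMSE increase); see
        :mod:`netstate.importance`."""
        from .importance import compute_raw_importance

        return compute_raw_importance(self, n_repeats=n_repeats, scope=scope)

    def summary(self) -> str:
        lines = [
            f"StateChangeResults: trait={self.trait}",
            f"  folds:               {len(self.fold_results)}",
            f"  rows:                {len(self.model.data)}",
            f"  mean R2 (defined):   {self.r2_mean:.3f}",
            f"  mean RMSE:           {self.rmse_mean:.3f}",
            f"  mean RMSE/range:     {self.rmse_normalized_mean:.3f}  (range {self.norm_range:.2f})",
        ]
        return "\n".join(lines)


def flag_informative(r2_values: Iterable[float], nrmse_values: Iterable[float]) -> bool:
    """A participant's five trait models are consistently informative when
    the worst explains ≥ 5% of variance and the mean normalized RMSE stays
    ≤ 25% of the outcome range; undefined R² fails conservatively."""
    r2 = np.asarray(list(r2_values), dtype=float)
    nrmse = np.asarray(list(nrmse_values), dtype=float)
    if r2.size == 0 or np.isnan(r2).any():
        return False
    return bool(r2.min() >= INFORMATIVE_R2_MIN and np.nanmean(nrmse) <= INFORMATIVE_NRMSE_MAX)


class CohortResults:
    """Bundle of the five trait-specific LOSO runs."""

    def __init__(self, results: dict[str, StateChangeResults]):
        self.results = results

    def __getitem__(self, trait: str) -> StateChangeResults:
        return self.results[trait]

    @property
    def traits(self) -> list[str]:
        return list(self.results)

    def cohort_table(self) -> pd.DataFrame:
        """Per-trait cohort averages (the headline performance numbers)."""
        return pd.DataFrame(
            {
                "trait": self.traits,
                "r2_mean": [self.results[t].r2_mean for t in self.traits],
                "r2_pooled": [self.results[t].r2_pooled for t in self.traits],
                "rmse_mean": [self.results[t].rmse_mean for t in self.traits],
                "rmse_normalized_mean": [self.results[t].rmse_normalized_mean for t in self.traits],
            }
        )

    def participant_table(self) -> pd.DataFrame:
        """Per-participant min/max/avg of R² and normalized RMSE across the
        five trait models, plus the consistently-informative flag; sorted
        by minimum R² (desc) then average normalized RMSE (asc)."""
        per_trait = {t: self.results[t].fold_table().set_index("participant_id") for t in self.traits}
        pids = sorted({pid for tbl in per_trait.values() for pid in tbl.index}, key=repr)
        rows = []
        for pid in pids:
            r2s = np.array([per_trait[t]["r2"].get(pid, np.nan) for t in self.traits], dtype=float)
            nrmses = np.array(
                [per_trait[t]["rmse_normalized"].get(pid, np.nan) for t in self.traits], dtype=float
            )
            defined = np.isfinite(r2s)
            rows.append(
                {
                    "participant_id": pid,
                    "r2_min": float(np.min(r2s[defined])) if defined.any() else np.nan,
                    "r2_max": float(np.max(r2s[defined])) if defined.any() else np.nan,
                    "r2_avg": float(np.mean(r2s[defined])) if defined.any() else np.nan,
                    "nrmse_min": float(np.nanmin(nrmses)),
                    "nrmse_max": float(np.nanmax(nrmses)),
                    "nrmse_avg": float(np.nanmean(nrmses)),
                    "informative": flag_informative(r2s, nrmses),
                }
            )
        table = pd.DataFrame(rows)
        return table.sort_values(
            ["r2_min", "nrmse_avg"], ascending=[False, True], na_position="last", kind="stable"
        ).reset_index(drop=True)

    def importance_profile(
        self, n_repeats: int = 10, scope: Literal["folds", "pooled"] = "folds"
    ) -> pd.DataFrame:
        from .importance import aggregate_profiles, scale_importances

        scaled = {
            t: scale_importances(self.results[t].importance(n_repeats=n_repeats, scope=scope))
            for t in self.traits
        }
        return aggregate_profiles(scaled)

    def summary(self) -> str:
        lines = ["CohortResults (five trait-specific LOSO runs)"]
        for t in self.traits:
            r = self.results[t]
            lines.append(
                f"  {t:<6} mean R2 {r.r2_mean:6.3f}   mean RMSE {r.rmse_mean:6.3f}"
                f"   mean RMSE/range {r.rmse_normalized_mean:6.3f}"
            )
        n_inf = int(self.participant_table()["informative"].sum())
        lines.append(f"  consistently informative participants: {n_inf}")
        return "\n".join(lines)


def pooled_outcome_range(outcomes: pd.DataFrame) -> float:
    """Observed RMSSD range pooled across the five trait columns."""
    vals = outcomes[list(TRAITS)].to_numpy(dtype=float)
    return float(np.nanmax(vals) - np.nanmin(vals))


def fit_all_traits(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    config: ModelConfig | None = None,
    keep_models: bool = True,
) -> CohortResults:
    """Fit the five trait-specific LOSO models with a shared pooled
    normalization range."""
    config = config or ModelConfig()
    if config.norm_range is None:
        config = replace(config, norm_range=pooled_outcome_range(outcomes))
    results = {
        trait: StateChangeModel.from_tables(features, outcomes, trait, config=config).fit(
            keep_models=keep_models
        )
        for trait in TRAITS
    }
    return CohortResults(results)


def fit_comparators(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Baseline learners under the identical LOSO scheme: a regularized
    linear model (elastic net on standardized features) and k-nearest-
    neighbor regression, both with library defaults.  Returns per
    (trait, model) cohort means on the same fold keys as the primary."""
    config = config or ModelConfig()
    norm_range = config.norm_range if config.norm_range is not None else pooled_outcome_range(outcomes)
    makers = {
        "glmnet": lambda: make_pipeline(StandardScaler(), ElasticNet()),
        "knn": lambda: make_pipeline(StandardScaler(), KNeighborsRegressor()),
    }
    rows = []
    for trait in TRAITS:
        table = join_rows(features, outcomes, trait)
        X = table[list(MATRIX_COLUMNS)]
        y = table[trait].to_numpy(dtype=float)
        for name, make in makers.items():
            fold_metrics = []
            for pid, train, test in loso_folds(table):
                reg = make()
                reg.fit(X.iloc[train], y[train])
                r2, rmse, nrmse, _ = evaluate_fold(reg, X.iloc[test], y[test], norm_range, config.r2_method)
                fold_metrics.append((pid, r2, rmse, nrmse))
            r2s = [m[1] for m in fold_metrics if np.isfinite(m[1])]
            rows.append(
                {
                    "trait": trait,
                    "model": name,
                    "r2_mean": float(np.mean(r2s)) if r2s else np.nan,
                    "rmse_mean": float(np.mean([m[2] for m in fold_metrics])),
                    "rmse_normalized_mean": float(np.mean([m[3] for m in fold_metrics])),
                }
            )
    return pd.DataFrame(rows)
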