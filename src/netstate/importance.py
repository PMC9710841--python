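"""Permutation feature importance, 0-100 scaling and cross-trait
aggregation.

Raw importance of a predictor is the mean increase in model RMSE when
that predictor's column is shuffled (its association with the outcome
broken), averaged over repeats; negative values — permutation noise —
are floored at zero.  Per trait model the raw vector is rescaled to
0-100 (max feature = 100, min = 0), and the five scaled per-trait
vectors are averaged feature-wise and ranked descending to give the
cross-trait importance profile.
"""

from __future__ import annotations

from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .model import StateChangeResults


def permutation_importance(model, X: pd.DataFrame, y: np.ndarray, feature: str,
                           n_repeats: int, rng: np.random.Generator) -> float:
    """Mean RMSE increase over ``n_repeats`` shuffles of one column,
    floored at zero.  A constant column scores exactly zero."""
    base_pred = np.asarray(model.predict(X), dtype=float)
    base_rmse = float(np.sqrt(np.mean((y - base_pred) ** 2)))
    col = X[feature].to_numpy()
    if np.all(col == col[0]):
        return 0.0
    deltas = []
    Xp = X.copy()
    for _ in range(n_repeats):
        Xp[feature] = rng.permutation(col)
        pred = np.asarray(model.predict(Xp), dtype=float)
        deltas.append(float(np.sqrt(np.mean((y - pred) ** 2))) - base_rmse)
    return max(0.0, float(np.mean(deltas)))


def compute_raw_importance(
    results: StateChangeResults,
    n_repeats: int = 10,
    scope: Literal["folds", "pooled"] = "folds",
) -> pd.Series:
    """Raw permutation importances for one trait's LOSO run.

    ``scope="folds"`` (default) evaluates each fold's model on its own
    training rows and averages across folds; ``scope="pooled"`` refits a
    single model on all rows with the first fold's winning parameters and
    evaluates once — much cheaper for large sweeps.  The permutation RNG
    is seeded per (fold, feature) so results do not depend on evaluation
    order.
    """
    model = results.model
    X_all, y_all = model.exog, model.endog
    feats = model.feature_columns
    if scope == "pooled":
        from .model import _make_regressor  # shared constructor, not public API

        params = results.fold_results[0].params
        reg = _make_regressor(params, model.config.seed)
        reg.fit(X_all, y_all)
        raw = {
            f: permutation_importance(
                reg, X_all, y_all, f, n_repeats,
                np.random.default_rng([model.config.seed, 0, k]),
            )
            for k, f in enumerate(feats)
        }
        return pd.Series(raw, name=results.trait)

    sums = {f: 0.0 for f in feats}
    n_folds = 0
    for fold in results.fold_results:
        if fold.model is None or fold.train_index is None:
            raise ValueError("fold models were not retained; refit with keep_models=True")
        Xf = X_all.iloc[fold.train_index]
        yf = y_all[fold.train_index]
        for k, f in enumerate(feats):
            rng = np.random.default_rng([fold.seed, k])
            sums[f] += permutation_importance(fold.model, Xf, yf, f, n_repeats, rng)
        n_folds += 1
    return pd.Series({f: s / n_folds for f, s in sums.items()}, name=results.trait)


def scale_importances(raw: pd.Series) -> pd.Series:
    """Linear rescale to 0-100 (min → 0, max → 100); an all-equal vector
    maps to all zeros."""
    if raw.empty:
        raise ValueError("no features to scale")
    lo, hi = float(raw.min()), float(raw.max())
    if hi == lo:
        return pd.Series(0.0, index=raw.index, name=raw.name)
    return 100.0 * (raw - lo) / (hi - lo)


def aggregate_profiles(scaled: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Cross-trait importance profile: one row per feature with the five
    scaled columns, their feature-wise mean ('average') and the dense rank
    by descending average (ties broken alphabetically by feature name)."""
    traits = list(scaled)
    index = scaled[traits[0]].index
    for t in traits[1:]:
        if not scaled[t].index.equals(index):
            raise ValueError("importance profiles cover different feature sets")
    table = pd.DataFrame({t: scaled[t] for t in traits})
    table["average"] = table[traits].mean(axis=1)
    table = table.rename_axis("feature").reset_index()
    table = table.sort_values(["average", "feature"], ascending=[False, True], kind="stable").reset_index(
        drop=True
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table
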