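"""Relative influence of survey factors on triad goodness-of-fit.

Which survey-design factors — site identity, depth, reef-wall aspect,
network size — determine how well the triad (shared-partner) term
reproduces a network?  A seeded random-forest regression of the
shared-partner goodness-of-fit p-value on the factors answers this through
permutation importance, normalized to percentages, plus univariate
partial-dependence curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .gof import FitBundle

__all__ = [
    "PREDICTORS",
    "assemble_predictor_table",
    "fit_ensemble",
    "relative_influence",
    "partial_dependence",
    "InfluenceModel",
]

PREDICTORS = ("site", "depth", "aspect", "n_vertices", "n_edges")
RESPONSE = "gwesp_gof_p"
_CATEGORICAL = ("site", "aspect")


def assemble_predictor_table(bundles: Sequence[FitBundle]) -> pd.DataFrame:
    """One row per network with a triad-model goodness-of-fit p-value.

    Networks whose covariate fit fell back to the no-triad model carry no
    shared-partner p-value and are excluded (their count is reported via a
    warning).  Edge counts are multiplicity-weighted: they count adjacency
    observations, not just distinct species pairs.
    """
    rows = []
    excluded = 0
    for bundle in bundles:
        p = bundle.gwesp_gof_p()
        if p is None:
            excluded += 1
            continue
        rows.append(
            {
                "label": f"{bundle.metadata.get('survey_id', '')}"
                f"@{bundle.metadata.get('depth', '')}",
                "site": str(bundle.metadata.get("site", "unknown")) or "unknown",
                "depth": float(bundle.metadata.get("depth", 0.0)),
                "aspect": str(bundle.metadata.get("aspect", "unknown")) or "unknown",
                "n_vertices": bundle.n_vertices,
                "n_edges": bundle.n_multi_edges,
                RESPONSE: float(p),
            }
        )
    if excluded:
        warnings.warn(f"{excluded} bundle(s) without a triad-model GoF were excluded")
    if len(rows) < 2:
        raise ValueError(
            f"need at least 2 networks with triad-model GoF, got {len(rows)}"
        )
    return pd.DataFrame(rows)


@dataclass
class InfluenceModel:
    """A fitted ensemble plus the encoding needed to query it."""

    forest: RandomForestRegressor
    table: pd.DataFrame
    predictors: tuple[str, ...]
    encodings: dict  # categorical predictor -> {level: code}
    seed: int

    def encode(self, table: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in self.predictors:
            col = table[name]
            if name in self.encodings:
                mapping = self.encodings[name]
                col = col.astype(str).map(lambda v: mapping.get(v, -1))
            cols.append(np.asarray(col, dtype=float))
        return np.column_stack(cols)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(self.encode(table))


def fit_ensemble(
    table: pd.DataFrame,
    predictors: Sequence[str] = PREDICTORS,
    n_trees: int = 500,
    seed: int = 0,
) -> InfluenceModel:
    """Fit the random-forest regression of the response on the predictors."""
    predictors = tuple(p for p in predictors if p in table.columns)
    if not predictors:
        raise ValueError("no usable predictors in table")
    encodings = {}
    for name in predictors:
        if name in _CATEGORICAL or table[name].dtype == object:
            levels = sorted(table[name].astype(str).unique())
            encodings[name] = {lev: k for k, lev in enumerate(levels)}
    model = InfluenceModel(
        forest=RandomForestRegressor(
            n_estimators=n_trees, random_state=seed, min_samples_leaf=5
        ),
        table=table.reset_index(drop=True),
        predictors=predictors,
        encodings=encodings,
        seed=seed,
    )
    X = model.encode(table)
    model.forest.fit(X, np.asarray(table[RESPONSE], dtype=float))
    return model


def relative_influence(
    table: pd.DataFrame | InfluenceModel,
    predictors: Sequence[str] = PREDICTORS,
    n_trees: int = 500,
    seed: int = 0,
    n_repeats: int = 10,
) -> dict[str, float]:
    """Cross-validated permutation importance, normalized to sum to 100.

    Each predictor column is permuted as a whole (categorical factors are
    never split across dummy columns) and the rise in held-out
    mean-squared prediction error over 5 folds, averaged over
    ``n_repeats`` permutations, is its raw importance.  Held-out (rather
    than training-set) error is essential: training-set permutation
    rewards whichever predictor the trees overfit, giving high-cardinality
    noise predictors spurious credit.  Negative values are clipped to
    zero and the shares scaled to percentages.  A constant response
    yields uniform shares with a warning.
    """
    if isinstance(table, InfluenceModel):
        model = table
    else:
        model = fit_ensemble(table, predictors=predictors, n_trees=n_trees, seed=seed)
    tab = model.table
    y = np.asarray(tab[RESPONSE], dtype=float)
    if np.ptp(y) == 0:
        warnings.warn("constant response: relative influences are uninformative")
        share = 100.0 / len(model.predictors)
        return {name: share for name in model.predictors}
    X = model.encode(tab)
    rng = np.random.default_rng(seed)
    n_rows = len(y)
    n_folds = min(5, n_rows)
    fold_of = rng.permutation(n_rows) % n_folds
    raw = {name: 0.0 for name in model.predictors}
    for fold in range(n_folds):
        train, test = fold_of != fold, fold_of == fold
        forest = RandomForestRegressor(
            n_estimators=max(50, model.forest.n_estimators // 2),
            random_state=seed + fold,
            min_samples_leaf=5,
        )
        forest.fit(X[train], y[train])
        base = float(np.mean((forest.predict(X[test]) - y[test]) ** 2))
        for k, name in enumerate(model.predictors):
            rises = []
            for _ in range(n_repeats):
                Xp = X[test].copy()
                Xp[:, k] = rng.permutation(Xp[:, k])
                rises.append(float(np.mean((forest.predict(Xp) - y[test]) ** 2)) - base)
            raw[name] += float(np.mean(rises)) / n_folds
    raw = {name: max(0.0, v) for name, v in raw.items()}
    total = sum(raw.values())
    # a total permutation rise that is negligible against the response
    # variance means the ensemble has no real out-of-sample skill; the
    # normalized ratios would be noise dressed up as percentages
    if total <= 0.02 * float(np.var(y)):
        warnings.warn("no predictor shows influence: reporting uniform shares")
        share = 100.0 / len(model.predictors)
        return {name: share for name in model.predictors}
    return {name: 100.0 * v / total for name, v in raw.items()}


def partial_dependence(
    model: InfluenceModel,
    predictor: str,
    grid: Sequence | None = None,
) -> pd.DataFrame:
    """Mean prediction with ``predictor`` clamped to each grid value.

    For categorical predictors the grid defaults to the observed levels;
    for numeric ones to an 11-point span of the observed range.
    """
    if predictor not in model.predictors:
        raise KeyError(f"unknown predictor {predictor!r}; have {model.predictors}")
    col = model.table[predictor]
    if grid is None:
        if predictor in model.encodings:
            grid = sorted(col.astype(str).unique())
        else:
            lo, hi = float(col.min()), float(col.max())
            grid = np.linspace(lo, hi, 11) if hi > lo else [lo]
    rows = []
    for value in grid:
        clamped = model.table.copy()
        clamped[predictor] = value
        rows.append({predictor: value, "mean_prediction": float(np.mean(model.predict(clamped)))})
    return pd.DataFrame(rows)
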