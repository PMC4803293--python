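"""The predictive battery linking HMR features to log RNA output.

Pieces, in the order a run uses them:

* exhaustive best-subset OLS over the six HMR features, returning the
  top model of every size 1..6 by R^2;
* a selection rule that keeps the *largest* per-size winner in which
  every coefficient is individually significant (two-sided t-test,
  alpha = 0.05 by default), with an override hook to force a stated
  subset;
* 10-fold cross-validated measured-vs-predicted Pearson correlation;
* LMG relative importance — each feature's average R^2 increment over
  all orders of entry, computed here by the equivalent subset-weighted
  closed form and normalized to sum 1;
* random-forest regression (mtry = 2, ntree = 500) with mean decrease
  in node impurity as importance and out-of-bag predictions for the
  honest measured-vs-predicted correlation;
* the void split: observations whose predicted log FPKM falls inside a
  closed window around the model intercept are moved to the "n" subset
  (void-state promoters whose measured RNA the chromatin features
  cannot explain), the rest form the "p" subset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from math import factorial
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .genomic_model import FEATURE_LABELS
from .hmr_engine import HmrMatrix

__all__ = [
    "SubsetModel",
    "fit_ols",
    "exhaustive_subset_search",
    "select_final_model",
    "RegressionReport",
    "cross_validate",
    "ImportanceVector",
    "lmg_importance",
    "RandomForestReport",
    "rf_regress",
    "VoidSplit",
    "split_void",
    "DEFAULT_VOID_WINDOWS",
]

#: Removal windows for predicted log(FPKM), per TATA-containing group.
DEFAULT_VOID_WINDOWS: dict[str, tuple[float, float]] = {
    "TATA": (0.7, 1.0),
    "TATA_DPE": (0.0, 1.0),
}


@dataclass(frozen=True)
class SubsetModel:
    """An OLS fit on a feature subset."""

    features: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    coef_p: dict[str, float]
    r2: float
    adj_r2: float
    selection_warning: bool = False  # set when no all-significant model existed

    def predict(self, matrix: HmrMatrix | pd.DataFrame) -> np.ndarray:
        data = matrix.data if isinstance(matrix, HmrMatrix) else matrix
        X = data[list(self.features)].to_numpy(dtype=float)
        beta = np.array([self.coefficients[f] for f in self.features])
        return self.intercept + X @ beta


def _design(matrix: HmrMatrix, features: Sequence[str], response: str):
    data = matrix.data
    if response not in data.columns:
        raise ValueError(f"matrix has no {response!r} column")
    unknown = [f for f in features if f not in data.columns]
    if unknown:
        raise ValueError(f"unknown features {unknown}")
    X = data[list(features)].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    return X, y


def fit_ols(
    features: Sequence[str], matrix: HmrMatrix, response: str = "log_fpkm"
) -> SubsetModel:
    """Ordinary least squares with intercept; two-sided t-test p-values."""
    features = tuple(features)
    if not features:
        raise ValueError("empty feature set")
    X, y = _design(matrix, features, response)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"n={n} observations insufficient for {p} features")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc)
    if rank < p + 1:
        collinear = []
        for j, f in enumerate(features):
            reduced = np.delete(Xc, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                collinear.append(f)
        raise ValueError(f"rank-deficient design; collinear features: {collinear or list(features)}")
    res = sm.OLS(y, Xc).fit()
    return SubsetModel(
        features=features,
        coefficients={f: float(res.params[j + 1]) for j, f in enumerate(features)},
        intercept=float(res.params[0]),
        coef_p={f: float(res.pvalues[j + 1]) for j, f in enumerate(features)},
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
    )


def exhaustive_subset_search(
    matrix: HmrMatrix,
    features: Sequence[str] = FEATURE_LABELS,
    response: str = "log_fpkm",
) -> dict[int, SubsetModel]:
    """Best (max R^2) OLS model of every subset size 1..len(features).

    All C(p, s) subsets are fitted; ties in R^2 are broken by the fixed
    canonical feature order (first enumerated subset wins).
    """
    features = tuple(features)
    winners: dict[int, SubsetModel] = {}
    for size in range(1, len(features) + 1):
        best: SubsetModel | None = None
        for subset in combinations(features, size):
            model = fit_ols(subset, matrix, response)
            if best is None or model.r2 > best.r2:
                best = model
        assert best is not None
        winners[size] = best
    return winners


def select_final_model(
    winners: Mapping[int, SubsetModel],
    alpha: float = 0.05,
    *,
    override: Sequence[str] | None = None,
    matrix: HmrMatrix | None = None,
    response: str = "log_fpkm",
) -> SubsetModel:
    """Largest per-size winner whose coefficients are all significant.

    Ties (several qualifying models of the same size) break by adjusted
    R^2. ``override`` forces a stated subset regardless of p-values —
    the hook for curated exceptions where a marginally non-significant
    variable is deliberately retained. If no model qualifies, the best
    single-feature model is returned flagged with ``selection_warning``.
    """
    if override is not None:
        if matrix is None:
            raise ValueError("override requires the matrix to refit on")
        return fit_ols(override, matrix, response)
    if not winners:
        raise ValueError("no candidate models")
    qualifying = [
        m for m in winners.values() if all(p < alpha for p in m.coef_p.values())
    ]
    if qualifying:
        return max(qualifying, key=lambda m: (len(m.features), m.adj_r2))
    fallback = winners[min(winners)]
    return replace(fallback, selection_warning=True)


@dataclass
class RegressionReport:
    """Cross-validated out-of-fold predictions and their agreement with y."""

    model: SubsetModel
    cv_predictions: np.ndarray  # aligned with the matrix rows, each predicted once
    fold_assignment: np.ndarray
    r: float
    r_pvalue: float
    fold_seed: int


def cross_validate(
    features: Sequence[str],
    matrix: HmrMatrix,
    folds: int = 10,
    seed: int = 0,
    response: str = "log_fpkm",
) -> RegressionReport:
    """K-fold CV of the OLS model; every observation predicted exactly once.

    Folds are a seeded uniform random partition (no stratification).
    Returns the refit-on-all-data model together with the out-of-fold
    predictions and the measured-vs-predicted Pearson r.
    """
    features = tuple(features)
    X, y = _design(matrix, features, response)
    n, p = X.shape
    if n < folds:
        raise ValueError(f"n={n} smaller than the number of folds {folds}")
    if n // folds < p + 1:
        raise ValueError(
            f"folds of ~{n // folds} observations are smaller than the "
            f"{p}-feature model plus intercept; use fewer folds"
        )
    preds = np.full(n, np.nan)
    assignment = np.empty(n, dtype=int)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    Xc = sm.add_constant(X, has_constant="add")
    for fold, (train, test) in enumerate(kf.split(X)):
        beta, *_ = np.linalg.lstsq(Xc[train], y[train], rcond=None)
        preds[test] = Xc[test] @ beta
        assignment[test] = fold
    assert not np.isnan(preds).any()
    r, r_p = stats.pearsonr(y, preds)
    return RegressionReport(
        model=fit_ols(features, matrix, response),
        cv_predictions=preds,
        fold_assignment=assignment,
        r=float(r),
        r_pvalue=float(r_p),
        fold_seed=seed,
    )


@dataclass(frozen=True)
class ImportanceVector:
    """Non-negative per-feature weights normalized to sum 1."""

    weights: dict[str, float]
    method: str  # "LMG" or "node_impurity"

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), dtype=float)
        if np.any(vals < -1e-12):
            raise ValueError("importance weights must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"importance weights must sum to 1, got {vals.sum()}")


def _subset_r2_cache(X: np.ndarray, y: np.ndarray) -> dict[frozenset, float]:
    """R^2 of the OLS fit (with intercept) for every subset of columns."""
    n, p = X.shape
    yc = y - y.mean()
    tss = float(yc @ yc)
    cache: dict[frozenset, float] = {frozenset(): 0.0}
    ones = np.ones((n, 1))
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            Xs = np.hstack([ones, X[:, subset]])
            beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
            resid = y - Xs @ beta
            cache[frozenset(subset)] = 1.0 - float(resid @ resid) / tss
    return cache


def lmg_importance(
    features: Sequence[str], matrix: HmrMatrix, response: str = "log_fpkm"
) -> ImportanceVector:
    """LMG relative importance of the features of a model.

    For feature k, LMG averages the R^2 increase from adding k after its
    predecessors over all p! entry orders; grouping orders by the set of
    predecessors gives the exact subset-weighted form used here:

        LMG_k = sum over S not containing k of
                |S|! (p - |S| - 1)! / p!  *  (R^2(S + k) - R^2(S)).

    Increments are non-negative, so the normalized weights are too.
    """
    features = tuple(features)
    if not (1 <= len(features) <= 10):
        raise ValueError("LMG enumeration supports 1..10 features")
    X, y = _design(matrix, features, response)
    p = X.shape[1]
    cache = _subset_r2_cache(X, y)
    raw = np.zeros(p)
    others = list(range(p))
    for k in range(p):
        rest = [j for j in others if j != k]
        for size in range(0, p):
            w = factorial(size) * factorial(p - size - 1) / factorial(p)
            for S in combinations(rest, size):
                s = frozenset(S)
                raw[k] += w * (cache[s | {k}] - cache[s])
    total = raw.sum()
    if total <= 0:
        raise ValueError("zero total R^2; LMG importance undefined")
    return ImportanceVector(
        weights={f: float(raw[j] / total) for j, f in enumerate(features)},
        method="LMG",
    )


@dataclass
class RandomForestReport:
    predictions: np.ndarray  # out-of-bag (default) or in-bag fitted values
    importance: ImportanceVector
    r: float
    r_pvalue: float
    prediction_kind: str
    seed: int


def rf_regress(
    matrix: HmrMatrix,
    features: Sequence[str] = FEATURE_LABELS,
    response: str = "log_fpkm",
    mtry: int = 2,
    ntree: int = 500,
    seed: int = 0,
    *,
    predictions: str = "oob",
) -> RandomForestReport:
    """Random-forest regression with node-impurity importance.

    ``predictions='oob'`` (default) scores each observation with trees
    that did not see it, the honest analogue of the linear CV;
    ``predictions='fit'`` uses resubstitution fitted values instead.
    Importance is the per-feature total decrease in node impurity
    (variance), normalized to sum 1. Deterministic under ``seed``.
    """
    features = tuple(features)
    X, y = _design(matrix, features, response)
    if X.shape[0] < 10:
        raise ValueError("need at least 10 observations for a forest")
    if np.ptp(y) == 0:
        raise ValueError("constant response; forest regression undefined")
    rf = RandomForestRegressor(
        n_estimators=ntree,
        max_features=mtry,
        oob_score=True,
        bootstrap=True,
        random_state=seed % (2**31),
        n_jobs=1,
    )
    rf.fit(X, y)
    if predictions == "oob":
        preds = rf.oob_prediction_
    elif predictions == "fit":
        preds = rf.predict(X)
    else:
        raise ValueError(f"unknown prediction kind {predictions!r}")
    imp = rf.feature_importances_
    imp = imp / imp.sum()
    r, r_p = stats.pearsonr(y, preds)
    return RandomForestReport(
        predictions=np.asarray(preds),
        importance=ImportanceVector(
            weights={f: float(imp[j]) for j, f in enumerate(features)},
            method="node_impurity",
        ),
        r=float(r),
        r_pvalue=float(r_p),
        prediction_kind=predictions,
        seed=seed,
    )


@dataclass
class VoidSplit:
    """Partition of a group's observations by predicted log FPKM window."""

    window: tuple[float, float]
    p_index: np.ndarray  # observations kept (prediction outside the window)
    n_index: np.ndarray  # observations removed (void window)

    @property
    def p_count(self) -> int:
        return int(self.p_index.size)

    @property
    def n_count(self) -> int:
        return int(self.n_index.size)


def split_void(
    matrix: HmrMatrix,
    predictions,
    window: tuple[float, float],
    *,
    closed: bool = True,
) -> VoidSplit:
    """Split observations by whether their prediction falls in the window.

    The window is a closed interval by default (``closed=False`` makes it
    open). The prediction vector must align one-to-one with the matrix
    rows — it is passed in, not recomputed, because linear and forest
    predictions yield different splits.
    """
    preds = np.asarray(predictions, dtype=float)
    if preds.shape != (len(matrix),):
        raise ValueError(
            f"prediction vector of length {preds.size} misaligned with "
            f"{len(matrix)} observations"
        )
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty void window {window}")
    if closed:
        in_window = (preds >= lo) & (preds <= hi)
    else:
        in_window = (preds > lo) & (preds < hi)
    idx = np.arange(len(matrix))
    return VoidSplit(window=(float(lo), float(hi)), p_index=idx[~in_window], n_index=idx[in_window])
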