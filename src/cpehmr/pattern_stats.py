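"""Cluster-structure statistics on HMR matrices.

The central statistic is a Monte-Carlo test of cluster tightness: the
observed within-cluster score W is the sum over samples of the squared
Euclidean distance to the nearest of k given centers; the null replaces
the centers with k points drawn uniformly (per dimension) within the
data's bounding box, and the empirical p-value is the add-one fraction
of null draws at least as tight as the observed score,

    p_emp = (1 + #{W_null <= W_obs}) / (n_iter + 1).

Because an empirical fraction cannot resolve below 1/(n_iter+1), a
Gaussian lower-tail approximation from the null moments is reported
alongside it; extremely small reported significance levels are only
reachable through such a parametric tail.

Also here: best-of-restarts k-means partitioning, hierarchical leaf
ordering for heatmap export, and the HMR > 0.5 frequency table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans

from .genomic_model import FEATURE_LABELS
from .hmr_engine import HmrMatrix

__all__ = [
    "ClusterTest",
    "cluster_null_test",
    "KmeansResult",
    "kmeans_partition",
    "hierarchical_order",
    "FrequencyTable",
    "frequency_table",
]


def nearest_center_wcss(points: np.ndarray, centers: np.ndarray) -> float:
    """Sum over samples of squared distance to the nearest center."""
    d2 = ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).sum())


@dataclass(frozen=True)
class ClusterTest:
    k: int
    observed_w: float
    null_samples: int
    null_mean: float
    null_sd: float
    p_empirical: float
    p_gaussian: float  # NaN when the null is degenerate (zero variance)
    seed: int


def cluster_null_test(
    points,
    centers,
    n_iter: int = 1_000_000,
    seed: int = 0,
    *,
    null: str = "bbox",
    chunk_size: int = 4096,
) -> ClusterTest:
    """Monte-Carlo significance of cluster tightness against random centers.

    ``null='bbox'`` draws each null center uniformly per dimension within
    the data's bounding box (the default; for HMR data this is close to
    the unit cube); ``null='unit'`` draws uniformly on [0, 1]^d.
    Reproducible under ``seed``.
    """
    points = np.asarray(points, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array")
    if centers.ndim != 2 or centers.shape[1] != points.shape[1]:
        raise ValueError("centers must share the points' dimension")
    k = centers.shape[0]
    if k < 1:
        raise ValueError("need at least one center")
    if k > points.shape[0]:
        raise ValueError(f"k={k} exceeds the number of points ({points.shape[0]})")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")

    if null == "bbox":
        lo, hi = points.min(axis=0), points.max(axis=0)
    elif null == "unit":
        lo = np.zeros(points.shape[1])
        hi = np.ones(points.shape[1])
    else:
        raise ValueError(f"unknown null scheme {null!r}")

    observed_w = nearest_center_wcss(points, centers)

    rng = np.random.default_rng(seed)
    n_le = 0
    total = 0.0
    total_sq = 0.0
    remaining = n_iter
    while remaining > 0:
        m = min(chunk_size, remaining)
        draw = rng.uniform(size=(m, k, points.shape[1]))
        draw = lo + draw * (hi - lo)
        # (m, n, k) squared distances; min over centers, sum over samples
        d2 = ((points[None, :, None, :] - draw[:, None, :, :]) ** 2).sum(axis=3)
        w = d2.min(axis=2).sum(axis=1)
        n_le += int((w <= observed_w).sum())
        total += float(w.sum())
        total_sq += float((w * w).sum())
        remaining -= m

    null_mean = total / n_iter
    null_var = max(0.0, total_sq / n_iter - null_mean**2)
    null_sd = float(np.sqrt(null_var))
    p_empirical = (1 + n_le) / (n_iter + 1)
    if null_sd > 0:
        p_gaussian = float(stats.norm.cdf((observed_w - null_mean) / null_sd))
    else:
        p_gaussian = float("nan")
    return ClusterTest(
        k=k,
        observed_w=observed_w,
        null_samples=n_iter,
        null_mean=null_mean,
        null_sd=null_sd,
        p_empirical=p_empirical,
        p_gaussian=p_gaussian,
        seed=seed,
    )


@dataclass
class KmeansResult:
    labels: np.ndarray  # relabelled so cluster 0 is the largest
    centers: np.ndarray
    wcss: float
    sizes: np.ndarray
    summaries: pd.DataFrame  # per-cluster feature means/medians


def kmeans_partition(
    points, k: int = 5, n_restarts: int = 1000, seed: int = 0, *,
    feature_names: Sequence[str] | None = None,
) -> KmeansResult:
    """Best-of-restarts k-means, clusters relabelled by size (descending).

    Restarts use nested seeds (seed, seed+1, ...), so increasing
    ``n_restarts`` can only improve (never worsen) the achieved WCSS.
    """
    points = np.asarray(points, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > points.shape[0]:
        raise ValueError(f"k={k} exceeds the number of rows ({points.shape[0]})")
    best = None
    for r in range(n_restarts):
        km = KMeans(n_clusters=k, n_init=1, random_state=(seed + r) % (2**31), init="random")
        km.fit(points)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    assert best is not None
    labels = best.labels_
    sizes = np.bincount(labels, minlength=k)
    # stable size-descending relabelling (ties broken by original label)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    centers = best.cluster_centers_[order]
    sizes = sizes[order]
    names = list(feature_names) if feature_names is not None else [
        f"x{i}" for i in range(points.shape[1])
    ]
    rows = []
    for c in range(k):
        sub = points[labels == c]
        row: dict[str, object] = {"cluster": c, "size": int(sizes[c])}
        for j, name in enumerate(names):
            row[f"mean_{name}"] = float(sub[:, j].mean())
            row[f"median_{name}"] = float(np.median(sub[:, j]))
        rows.append(row)
    return KmeansResult(
        labels=labels,
        centers=centers,
        wcss=float(best.inertia_),
        sizes=sizes,
        summaries=pd.DataFrame(rows),
    )


def hierarchical_order(
    points, *, method: str = "complete", metric: str = "euclidean"
) -> np.ndarray:
    """Leaf order of an agglomerative tree, for heatmap row ordering."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("need at least 2 rows to order")
    Z = linkage(points, method=method, metric=metric)
    return np.asarray(leaves_list(Z))


@dataclass
class FrequencyTable:
    """Fraction of observations with HMR above a threshold, by (group, feature)."""

    threshold: float
    data: pd.DataFrame  # index: group, columns: feature labels, values in [0, 1]


def frequency_table(
    matrices: Mapping[str, HmrMatrix],
    threshold: float = 0.5,
    *,
    per_promoter: bool = False,
) -> FrequencyTable:
    """Fraction of observations with HMR strictly above ``threshold``.

    The default denominator is promoter x stage observations. With
    ``per_promoter=True`` a promoter counts once, when its stage-median
    HMR exceeds the threshold.
    """
    if not matrices:
        raise ValueError("no matrices supplied")
    rows = {}
    for group, matrix in matrices.items():
        if len(matrix) == 0:
            raise ValueError(f"empty matrix for group {group}")
        if per_promoter:
            med = matrix.data.groupby("promoter_id")[list(FEATURE_LABELS)].median()
            rows[group] = (med > threshold).mean()
        else:
            rows[group] = (matrix.data[list(FEATURE_LABELS)] > threshold).mean()
    data = pd.DataFrame(rows).T
    data.index.name = "group"
    return FrequencyTable(threshold=threshold, data=data)
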