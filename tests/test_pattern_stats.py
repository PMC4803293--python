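import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpehmr.genomic_model import FEATURE_LABELS, Stage
from cpehmr.hmr_engine import HmrMatrix
from cpehmr.pattern_stats import (
    cluster_null_test,
    frequency_table,
    hierarchical_order,
    kmeans_partition,
    nearest_center_wcss,
)


class TestClusterNullTest:
    def test_points_equal_centers_gives_minimal_p(self):
        points = np.array([[0.1, 0.2], [0.8, 0.9], [0.5, 0.5]])
        res = cluster_null_test(points, points, n_iter=1000, seed=0)
        assert res.observed_w == 0.0
        assert res.p_empirical == pytest.approx(1 / 1001)

    def test_k_larger_than_n_is_error(self):
        points = np.random.default_rng(0).uniform(size=(3, 2))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_null_test(points, np.zeros((4, 2)), n_iter=1000)

    def test_dimension_mismatch_is_error(self):
        points = np.zeros((5, 2))
        with pytest.raises(ValueError, match="dimension"):
            cluster_null_test(points, np.zeros((2, 3)), n_iter=1000)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(5)
        points = rng.uniform(size=(20, 3))
        centers = rng.uniform(size=(2, 3))
        a = cluster_null_test(points, centers, n_iter=2000, seed=42)
        b = cluster_null_test(points, centers, n_iter=2000, seed=42)
        assert a == b

    def test_invariant_to_common_permutation(self):
        rng = np.random.default_rng(6)
        points = rng.uniform(size=(30, 4))
        centers = rng.uniform(size=(3, 4))
        perm = rng.permutation(30)
        a = cluster_null_test(points, centers, n_iter=1500, seed=9)
        b = cluster_null_test(points[perm], centers, n_iter=1500, seed=9)
        assert a.p_empirical == b.p_empirical
        assert a.observed_w == pytest.approx(b.observed_w)

    def test_one_dim_toy_against_independent_monte_carlo(self):
        """{0,0,1,1} with centers {0,1}: brute-force MC oracle agreement."""
        points = np.array([[0.0], [0.0], [1.0], [1.0]])
        centers = np.array([[0.0], [1.0]])
        n_iter = 10_000
        res = cluster_null_test(points, centers, n_iter=n_iter, seed=3)

        # independent re-implementation, plain loops over draws
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(n_iter):
            c = rng.uniform(0.0, 1.0, size=2)
            w = sum(min((p - c[0]) ** 2, (p - c[1]) ** 2) for p in points.ravel())
            if w <= res.observed_w:
                hits += 1
        p_oracle = (1 + hits) / (n_iter + 1)
        # binomial 99% agreement bounds around the oracle estimate
        p = res.p_empirical
        se = np.sqrt(p_oracle * (1 - p_oracle) / n_iter)
        assert abs(p - p_oracle) < 2.58 * 2 * se + 1e-12

    def test_gaussian_tail_defined_and_small_for_tight_clusters(self):
        # high-dimensional tight blobs: the null W concentrates (relative
        # spread ~ 1/sqrt(d)), so the z-score grows with dimension
        rng = np.random.default_rng(0)
        d = 24
        blob = np.vstack(
            [rng.normal(loc, 0.02, size=(300, d)) for loc in (0.1, 0.9)]
        )
        centers = np.array([[0.1] * d, [0.9] * d])
        res = cluster_null_test(blob, centers, n_iter=2000, seed=1)
        # the parametric tail resolves far below the 1/(n_iter+1) floor
        assert res.p_gaussian < 1e-6 < res.p_empirical
        assert res.p_empirical == pytest.approx(1 / 2001)

    def test_degenerate_null_marks_gaussian_undefined(self):
        points = np.tile([[0.5, 0.5]], (5, 1))
        res = cluster_null_test(points, points[:1], n_iter=1000, seed=0)
        assert np.isnan(res.p_gaussian)


class TestKmeans:
    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.1, 0.02, size=(20, 3))
        b = rng.normal(0.9, 0.02, size=(30, 3))
        res = kmeans_partition(np.vstack([a, b]), k=2, n_restarts=10, seed=0)
        assert set(np.unique(res.labels[:20])) != set(np.unique(res.labels[20:]))
        assert res.sizes.tolist() == [30, 20]  # size-descending relabelling

    def test_k_equals_n_gives_zero_wcss(self):
        points = np.random.default_rng(3).uniform(size=(6, 2))
        res = kmeans_partition(points, k=6, n_restarts=5, seed=0)
        assert res.wcss == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_under_seed(self):
        points = np.random.default_rng(4).uniform(size=(40, 5))
        a = kmeans_partition(points, k=3, n_restarts=8, seed=7)
        b = kmeans_partition(points, k=3, n_restarts=8, seed=7)
        assert np.array_equal(a.labels, b.labels)
        assert a.wcss == b.wcss

    def test_wcss_non_increasing_in_restarts(self):
        points = np.random.default_rng(8).uniform(size=(60, 4))
        w = [
            kmeans_partition(points, k=4, n_restarts=r, seed=11).wcss
            for r in (1, 3, 10)
        ]
        assert w[0] >= w[1] >= w[2]

    def test_invalid_k(self):
        points = np.zeros((5, 2))
        with pytest.raises(ValueError):
            kmeans_partition(points, k=0)
        with pytest.raises(ValueError):
            kmeans_partition(points, k=6)


class TestHierarchicalOrder:
    def test_identical_blocks_stay_contiguous(self):
        block_a = np.tile([0.1, 0.1, 0.1], (4, 1))
        block_b = np.tile([0.9, 0.9, 0.9], (5, 1))
        points = np.vstack([block_a, block_b])
        order = hierarchical_order(points + np.random.default_rng(0).normal(0, 1e-3, points.shape))
        labels = (np.asarray(order) >= 4).astype(int)
        assert np.abs(np.diff(labels)).sum() == 1  # one switch between blocks

    def test_reversal_preserves_blocks(self):
        rng = np.random.default_rng(1)
        points = np.vstack(
            [rng.normal(0.1, 0.01, (3, 2)), rng.normal(0.9, 0.01, (3, 2))]
        )
        fwd = hierarchical_order(points)
        rev = hierarchical_order(points[::-1])
        fwd_blocks = [tuple(sorted(fwd[:3])), tuple(sorted(fwd[3:]))]
        rev_blocks = [tuple(sorted(5 - rev[:3])), tuple(sorted(5 - rev[3:]))]
        assert sorted(fwd_blocks) == sorted(rev_blocks)

    def test_two_rows(self):
        order = hierarchical_order(np.array([[0.0], [1.0]]))
        assert sorted(order.tolist()) == [0, 1]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_order(np.array([[1.0, 2.0]]))


def _matrix(values_by_feature, group="Inr"):
    n = len(next(iter(values_by_feature.values())))
    data = pd.DataFrame(values_by_feature)
    for lab in FEATURE_LABELS:
        if lab not in data:
            data[lab] = 0.0
    data.insert(0, "promoter_id", [f"p{i}" for i in range(n)])
    data.insert(1, "stage", [Stage.E0h] * n)
    return HmrMatrix(group=group, data=data)


class TestFrequencyTable:
    def test_all_zero(self):
        m = _matrix({"H3K4me3_CP": [0.0, 0.0]})
        table = frequency_table({"Inr": m})
        assert (table.data.to_numpy() == 0).all()

    def test_all_one(self):
        m = _matrix({lab: [1.0, 1.0] for lab in FEATURE_LABELS})
        table = frequency_table({"Inr": m})
        assert (table.data.to_numpy() == 1).all()

    def test_direct_count(self):
        m = _matrix({"H3K4me3_CP": [0.2, 0.6, 0.7, 0.4]})
        table = frequency_table({"Inr": m})
        assert table.data.loc["Inr", "H3K4me3_CP"] == pytest.approx(0.5)

    def test_threshold_is_strict(self):
        m = _matrix({"H3K4me3_CP": [0.5, 0.5]})
        assert frequency_table({"Inr": m}).data.loc["Inr", "H3K4me3_CP"] == 0.0

    def test_monotone_non_increasing_in_threshold(self, study_matrices):
        t1 = frequency_table(study_matrices, threshold=0.3).data
        t2 = frequency_table(study_matrices, threshold=0.5).data
        t3 = frequency_table(study_matrices, threshold=0.7).data
        assert (t1.to_numpy() >= t2.to_numpy()).all()
        assert (t2.to_numpy() >= t3.to_numpy()).all()

    def test_per_promoter_mode(self):
        m = _matrix({"H3K4me3_CP": [0.9, 0.9, 0.1, 0.2]})
        m.data["promoter_id"] = ["a", "a", "b", "b"]
        table = frequency_table({"Inr": m}, per_promoter=True)
        assert table.data.loc["Inr", "H3K4me3_CP"] == pytest.approx(0.5)


def test_wcss_helper_matches_manual_sum():
    points = np.array([[0.0, 0.0], [1.0, 1.0]])
    centers = np.array([[0.0, 0.0], [2.0, 2.0]])
    assert nearest_center_wcss(points, centers) == pytest.approx(0.0 + 2.0)
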