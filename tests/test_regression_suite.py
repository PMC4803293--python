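from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest

from cpehmr.genomic_model import FEATURE_LABELS, Stage
from cpehmr.hmr_engine import HmrMatrix
from cpehmr.regression_suite import (
    ImportanceVector,
    cross_validate,
    exhaustive_subset_search,
    fit_ols,
    lmg_importance,
    rf_regress,
    select_final_model,
    split_void,
)


def make_matrix(X, y, feature_names=None):
    names = feature_names or list(FEATURE_LABELS[: X.shape[1]])
    data = pd.DataFrame(X, columns=names)
    for lab in FEATURE_LABELS:
        if lab not in data:
            data[lab] = 0.5
    n = len(data)
    data.insert(0, "promoter_id", [f"p{i // 11}" for i in range(n)])
    data.insert(1, "stage", [list(Stage)[i % 11] for i in range(n)])
    data["log_fpkm"] = y
    # allow arbitrary synthetic X outside [0,1] by clipping display columns only
    data[names] = np.clip(X, 0.0, 1.0) if (X < 0).any() or (X > 1).any() else X
    return HmrMatrix(group="Inr", data=data)


def brute_force_r2(X, y, subset):
    Xc = np.column_stack([np.ones(len(X)), X[:, subset]])
    beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ beta
    return 1 - resid @ resid / ((y - y.mean()) ** 2).sum()


class TestFitOls:
    def test_noiseless_exact_fit(self, rng):
        x = rng.uniform(size=220)
        y = 2.0 * x + 1.0
        model = fit_ols(["H3K4me3_CP"], make_matrix(x[:, None], y))
        assert model.coefficients["H3K4me3_CP"] == pytest.approx(2.0)
        assert model.intercept == pytest.approx(1.0)
        assert model.r2 == pytest.approx(1.0)

    def test_planted_coefficients_within_three_se(self, rng):
        n = 264
        X = rng.uniform(size=(n, 3))
        beta = np.array([2.98, 1.61, -0.80])
        y = 0.82 + X @ beta + rng.normal(0, 1, n)
        names = ["H3K27ac_T", "H3K4me3_CP", "H3K27me3_CP"]
        model = fit_ols(names, make_matrix(X, y, names))
        # rough SE bound: sigma / (sd_x * sqrt(n)) with sd_x = sqrt(1/12)
        se = 1.0 / (np.sqrt(1 / 12) * np.sqrt(n))
        for name, b in zip(names, beta):
            assert abs(model.coefficients[name] - b) < 3.5 * se

    def test_constant_feature_is_rank_deficient(self):
        X = np.full((50, 1), 0.5)
        y = np.arange(50.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_ols(["H3K4me3_CP"], make_matrix(X, y))

    def test_duplicated_feature_named_in_error(self, rng):
        x = rng.uniform(size=60)
        X = np.column_stack([x, x])
        names = ["H3K4me3_CP", "H3K27ac_CP"]
        with pytest.raises(ValueError, match="H3K4me3_CP"):
            fit_ols(names, make_matrix(X, x, names))

    def test_too_few_observations(self, rng):
        X = rng.uniform(size=(3, 3))
        with pytest.raises(ValueError, match="insufficient"):
            fit_ols(list(FEATURE_LABELS[:3]), make_matrix(X, np.ones(3)))


class TestExhaustiveSearch:
    def test_single_signal_wins_size_one(self, rng):
        n = 300
        X = rng.uniform(size=(n, 6))
        y = 3.0 * X[:, 0] + rng.normal(0, 0.1, n)
        winners = exhaustive_subset_search(make_matrix(X, y))
        assert winners[1].features == (FEATURE_LABELS[0],)

    def test_matches_independent_brute_force(self, rng):
        for _ in range(5):
            n = 60
            X = rng.uniform(size=(n, 6))
            y = X @ rng.normal(size=6) + rng.normal(0, 0.5, n)
            winners = exhaustive_subset_search(make_matrix(X, y))
            for size in range(1, 7):
                best_r2, best_sub = max(
                    (brute_force_r2(X, y, list(sub)), sub)
                    for sub in combinations(range(6), size)
                )
                assert winners[size].r2 == pytest.approx(best_r2)
                assert winners[size].features == tuple(
                    FEATURE_LABELS[j] for j in best_sub
                )

    def test_duplicate_signals_tie_broken_by_feature_order(self, rng):
        n = 150
        x = rng.uniform(size=n)
        X = np.column_stack([x, x + rng.normal(0, 1e-9, n)])
        names = ["H3K4me3_CP", "H3K27ac_CP"]
        winners = exhaustive_subset_search(
            make_matrix(X, 2 * x + rng.normal(0, 0.2, n), names), features=names
        )
        assert winners[1].features in {("H3K4me3_CP",), ("H3K27ac_CP",)}


class TestSelectFinalModel:
    def test_planted_support_selected_at_large_n(self, rng):
        n = 2000
        X = rng.uniform(size=(n, 6))
        y = 0.5 + 3.0 * X[:, 4] + 2.0 * X[:, 0] + rng.normal(0, 1, n)
        winners = exhaustive_subset_search(make_matrix(X, y))
        model = select_final_model(winners, alpha=0.05)
        assert set(model.features) >= {FEATURE_LABELS[4], FEATURE_LABELS[0]}
        assert not model.selection_warning

    def test_pure_noise_takes_warning_path(self, rng):
        n = 200
        X = rng.uniform(size=(n, 6))
        y = rng.normal(size=n)
        winners = exhaustive_subset_search(make_matrix(X, y))
        model = select_final_model(winners, alpha=1e-6)
        assert model.selection_warning
        assert len(model.features) == 1

    def test_override_forces_stated_subset(self, rng):
        n = 120
        X = rng.uniform(size=(n, 6))
        y = rng.normal(size=n)
        matrix = make_matrix(X, y)
        winners = exhaustive_subset_search(matrix)
        override = ("H3K27ac_T", "H3K4me3_CP", "H3K27me3_CP")
        model = select_final_model(winners, override=override, matrix=matrix)
        assert model.features == override

    def test_all_significant_rule(self, rng):
        n = 400
        X = rng.uniform(size=(n, 3))
        names = list(FEATURE_LABELS[:3])
        y = 4.0 * X[:, 0] + rng.normal(0, 1, n)  # only one real signal
        winners = exhaustive_subset_search(make_matrix(X, y, names), features=names)
        model = select_final_model(winners, alpha=0.05)
        assert all(p < 0.05 for p in model.coef_p.values())


class TestCrossValidate:
    def test_noiseless_linear_data(self, rng):
        n = 220
        X = rng.uniform(size=(n, 2))
        y = 1.0 + X @ np.array([2.0, -1.0])
        names = list(FEATURE_LABELS[:2])
        report = cross_validate(names, make_matrix(X, y, names), seed=0)
        assert report.r > 0.999

    def test_every_observation_predicted_exactly_once(self, rng):
        n = 264
        X = rng.uniform(size=(n, 3))
        y = rng.normal(size=n)
        report = cross_validate(list(FEATURE_LABELS[:3]), make_matrix(X, y), seed=1)
        assert report.cv_predictions.shape == (n,)
        assert np.isfinite(report.cv_predictions).all()
        assert np.bincount(report.fold_assignment).sum() == n
        assert len(np.unique(report.fold_assignment)) == 10

    def test_null_correlation_shows_no_positive_skill(self, rng):
        # out-of-fold predictions of pure noise carry a small *negative*
        # bias (fold means anti-correlate with held-out residuals), so the
        # null band is one-sided above and widened below
        n = 264
        X = rng.uniform(size=(n, 3))
        y = rng.normal(size=n)
        report = cross_validate(list(FEATURE_LABELS[:3]), make_matrix(X, y), seed=2)
        assert report.r < 3 / np.sqrt(n)
        assert report.r > -0.4

    def test_planted_r_squared_gives_expected_cv_correlation(self, rng):
        # population R^2 = 0.36 -> CV r concentrates near 0.6
        n = 264
        X = rng.uniform(size=(n, 1))
        sd_x = np.sqrt(1 / 12)
        beta = 3.0
        signal_var = (beta * sd_x) ** 2
        noise_sd = np.sqrt(signal_var * (1 - 0.36) / 0.36)
        rs = []
        for seed in range(10):
            rng2 = np.random.default_rng(seed)
            Xs = rng2.uniform(size=(n, 1))
            y = beta * Xs[:, 0] + rng2.normal(0, noise_sd, n)
            names = ["H3K27ac_T"]
            rs.append(cross_validate(names, make_matrix(Xs, y, names), seed=seed).r)
        assert abs(np.mean(rs) - 0.6) < 0.1

    def test_too_many_folds_for_small_data(self, rng):
        X = rng.uniform(size=(12, 5))
        with pytest.raises(ValueError, match="fewer folds"):
            cross_validate(list(FEATURE_LABELS[:5]), make_matrix(X, np.ones(12)), folds=10)


def lmg_by_permutation_enumeration(X, y):
    """Independent LMG oracle: average R^2 increment over all entry orders."""
    p = X.shape[1]
    raw = np.zeros(p)
    perms = list(permutations(range(p)))
    for order in perms:
        seen = []
        prev = 0.0
        for k in order:
            seen.append(k)
            cur = brute_force_r2(X, y, seen)
            raw[k] += cur - prev
            prev = cur
    raw /= len(perms)
    return raw / raw.sum()


class TestLmgImportance:
    def test_single_feature_gets_all_importance(self, rng):
        x = rng.uniform(size=100)
        y = x + rng.normal(0, 0.2, 100)
        imp = lmg_importance(["H3K4me3_CP"], make_matrix(x[:, None], y))
        assert imp.weights["H3K4me3_CP"] == pytest.approx(1.0)
        assert imp.method == "LMG"

    def test_exchangeable_features_split_evenly(self, rng):
        n = 1000
        X = rng.uniform(size=(n, 2))
        y = X[:, 0] + X[:, 1] + rng.normal(0, 0.3, n)
        names = list(FEATURE_LABELS[:2])
        imp = lmg_importance(names, make_matrix(X, y, names))
        assert imp.weights[names[0]] == pytest.approx(0.5, abs=0.02)

    def test_matches_permutation_enumeration_oracle(self, rng):
        for _ in range(5):
            n = 60
            L = rng.normal(size=(4, 4))
            X = rng.normal(size=(n, 4)) @ L  # correlated design
            X = (X - X.min(0)) / (X.max(0) - X.min(0))
            y = X @ rng.normal(size=4) + rng.normal(0, 0.5, n)
            names = list(FEATURE_LABELS[:4])
            imp = lmg_importance(names, make_matrix(X, y, names))
            oracle = lmg_by_permutation_enumeration(X, y)
            got = np.array([imp.weights[nm] for nm in names])
            assert np.abs(got - oracle).max() < 1e-10

    def test_orthogonal_design_equals_r2_shares(self, rng):
        # independent features: LMG weight == each feature's share of R^2
        n = 60_000
        X = rng.uniform(size=(n, 3))
        y = 3.0 * X[:, 0] + 2.0 * X[:, 1] + 1.0 * X[:, 2] + rng.normal(0, 1, n)
        names = list(FEATURE_LABELS[:3])
        imp = lmg_importance(names, make_matrix(X, y, names))
        shares = np.array([9.0, 4.0, 1.0]) / 14.0
        got = np.array([imp.weights[nm] for nm in names])
        assert np.abs(got - shares).max() < 0.02

    def test_weights_nonnegative_and_normalized(self, study_matrices):
        imp = lmg_importance(list(FEATURE_LABELS[:4]), study_matrices["Inr"])
        vals = np.array(list(imp.weights.values()))
        assert (vals >= 0).all()
        assert vals.sum() == pytest.approx(1.0, abs=1e-9)


class TestImportanceVector:
    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ImportanceVector({"a": 0.5, "b": 0.4}, "LMG")

    def test_rejects_negative(self):
        with pytest.raises(ValueError, match="non-negative"):
            ImportanceVector({"a": 1.5, "b": -0.5}, "LMG")


class TestRandomForest:
    def test_strong_predictor_dominates_importance(self, rng):
        n = 300
        X = rng.uniform(size=(n, 6))
        y = 5.0 * X[:, 2] + rng.normal(0, 0.3, n)
        report = rf_regress(make_matrix(X, y), ntree=100, seed=0)
        top = max(report.importance.weights, key=report.importance.weights.get)
        assert top == FEATURE_LABELS[2]
        assert report.r > 0.8

    def test_pure_noise_oob_r_within_null_bound(self, rng):
        n = 400
        X = rng.uniform(size=(n, 6))
        y = rng.normal(size=n)
        report = rf_regress(make_matrix(X, y), ntree=100, seed=1)
        assert abs(report.r) < 4 / np.sqrt(n)

    def test_deterministic_under_seed(self, rng):
        n = 120
        X = rng.uniform(size=(n, 6))
        y = X[:, 0] + rng.normal(0, 0.5, n)
        a = rf_regress(make_matrix(X, y), ntree=50, seed=9)
        b = rf_regress(make_matrix(X, y), ntree=50, seed=9)
        assert a.importance.weights == b.importance.weights
        assert np.array_equal(a.predictions, b.predictions)

    def test_constant_response_is_error(self, rng):
        X = rng.uniform(size=(50, 6))
        with pytest.raises(ValueError, match="constant response"):
            rf_regress(make_matrix(X, np.ones(50)))

    def test_in_bag_prediction_mode(self, rng):
        n = 120
        X = rng.uniform(size=(n, 6))
        y = X[:, 0] + rng.normal(0, 0.5, n)
        oob = rf_regress(make_matrix(X, y), ntree=50, seed=0, predictions="oob")
        fit = rf_regress(make_matrix(X, y), ntree=50, seed=0, predictions="fit")
        assert fit.r >= oob.r  # resubstitution is optimistic


class TestSplitVoid:
    def test_window_membership(self, rng):
        X = rng.uniform(size=(3, 6))
        matrix = make_matrix(X, np.zeros(3))
        split = split_void(matrix, [0.5, 0.8, 1.2], (0.7, 1.0))
        assert split.n_index.tolist() == [1]
        assert split.p_index.tolist() == [0, 2]
        assert split.p_count + split.n_count == 3

    def test_total_window_empties_p_subset(self, rng):
        X = rng.uniform(size=(5, 6))
        matrix = make_matrix(X, np.zeros(5))
        split = split_void(matrix, np.zeros(5), (-np.inf, np.inf))
        assert split.p_count == 0 and split.n_count == 5

    def test_boundary_closed_vs_open(self, rng):
        matrix = make_matrix(rng.uniform(size=(2, 6)), np.zeros(2))
        closed = split_void(matrix, [0.7, 1.0], (0.7, 1.0))
        opened = split_void(matrix, [0.7, 1.0], (0.7, 1.0), closed=False)
        assert closed.n_count == 2 and opened.n_count == 0

    def test_misaligned_predictions_error(self, rng):
        matrix = make_matrix(rng.uniform(size=(4, 6)), np.zeros(4))
        with pytest.raises(ValueError, match="misaligned"):
            split_void(matrix, [0.5, 0.8], (0.7, 1.0))
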