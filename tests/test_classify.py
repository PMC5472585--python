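"""Cross-validation protocol, feature selection, curves, importances."""

import numpy as np
import pytest

from rxnaudit.classify import (
    FeatureMatrix,
    ModelSpec,
    correlation_rank,
    cv_train_eval,
    error_vs_dataset_size,
    error_vs_num_features,
    gini_importance_stability,
    lasso_logistic_check,
    pca_projection,
    rf_regression_rmse,
    stratified_nested_subsamples,
)
from rxnaudit.synthetic_data import planted_features

FAST_RF = ModelSpec(n_estimators=50)


def _planted(n=600, noise=0.0, seed=0):
    X, y, info = planted_features(n, label_noise=noise, seed=seed)
    names = info + [f"noise_{j:02d}" for j in range(90)]
    return FeatureMatrix.from_array(X, names), np.asarray(y), info


class TestCorrelationRank:
    def test_perfect_correlate_ranks_first(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        X = np.column_stack([rng.normal(size=200), y.astype(float)])
        fm = FeatureMatrix.from_array(X, ["noise", "copy"])
        ranked = correlation_rank(fm, y)
        assert ranked[0][0] == "copy"
        assert abs(ranked[0][1]) == pytest.approx(1.0)

    def test_constant_column_ranks_last_with_zero(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        X = np.column_stack([y.astype(float), np.full(100, 3.0)])
        ranked = correlation_rank(FeatureMatrix.from_array(X, ["sig", "const"]), y)
        assert ranked[-1] == ("const", 0.0)

    def test_anticorrelate_beats_noise(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 500)
        X = np.column_stack([(1 - y).astype(float), rng.normal(size=500)])
        ranked = correlation_rank(FeatureMatrix.from_array(X, ["anti", "noise"]), y)
        assert ranked[0][0] == "anti"

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            correlation_rank(FeatureMatrix.from_array(np.ones((5, 2))), np.ones(5))


class TestCvTrainEval:
    def test_separable_problem_near_zero_error(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 400)
        X = np.column_stack([y.astype(float), rng.normal(size=400)])
        res = cv_train_eval(FeatureMatrix.from_array(X), y, FAST_RF, seed=0)
        assert res.mean_error < 0.02

    def test_coin_flip_labels_near_half(self):
        rng = np.random.default_rng(4)
        n = 4000
        X = rng.normal(size=(n, 5))
        y = rng.integers(0, 2, n)
        res = cv_train_eval(FeatureMatrix.from_array(X), y, FAST_RF, seed=1)
        assert res.mean_error == pytest.approx(0.5, abs=0.03)

    def test_deterministic_given_seed(self):
        fm, y, _ = _planted(300)
        a = cv_train_eval(fm, y, FAST_RF, seed=7)
        b = cv_train_eval(fm, y, FAST_RF, seed=7)
        assert a.fold_errors == b.fold_errors
        assert a.test_fold_ids == b.test_fold_ids

    def test_row_permutation_invariance(self):
        fm, y, _ = _planted(300)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(y))
        fm_p = fm.take_rows(perm)
        a = cv_train_eval(fm, y, FAST_RF, seed=3)
        b = cv_train_eval(fm_p, y[perm], FAST_RF, seed=3)
        assert a.mean_error == b.mean_error
        assert a.fold_errors == b.fold_errors

    def test_folds_partition_rows(self):
        fm, y, _ = _planted(200)
        res = cv_train_eval(fm, y, FAST_RF, seed=0)
        ids = [i for fold in res.test_fold_ids for i in fold]
        assert sorted(ids) == sorted(fm.row_ids)
        sizes = [len(f) for f in res.test_fold_ids]
        assert max(sizes) - min(sizes) <= 1  # four equal parts

    def test_selection_uses_training_rows_only(self):
        """Per-fold selected features must be recomputable from the training
        rows alone: no test-fold information enters the ranking."""
        fm, y, _ = _planted(240, seed=9)
        res = cv_train_eval(
            fm, y, ModelSpec(n_estimators=20, select_k=10), seed=2
        )
        order = np.asarray(sorted(range(len(fm.row_ids)), key=lambda i: fm.row_ids[i]))
        fm_s, y_s = fm.take_rows(order), y[order]
        id_pos = {rid: i for i, rid in enumerate(fm_s.row_ids)}
        for fold, test_ids in enumerate(res.test_fold_ids):
            train_idx = [i for rid, i in id_pos.items() if rid not in set(test_ids)]
            expected = [
                n for n, _ in correlation_rank(fm_s.take_rows(train_idx), y_s[train_idx])[:10]
            ]
            assert res.selected_features[fold] == expected

    def test_too_small_class_errors(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            cv_train_eval(FeatureMatrix.from_array(X), y, FAST_RF)


class TestCurves:
    def test_error_vs_num_features_plateau(self):
        fm, y, _ = _planted(1500, seed=10)
        curve = error_vs_num_features(fm, y, [5, 10, 50, 100], FAST_RF, seed=0)
        assert curve.x == [5.0, 10.0, 50.0, 100.0]
        # errors fall until the informative block is covered, then plateau
        pooled = np.hypot(curve.yerr[2], curve.yerr[3])
        assert abs(curve.y[2] - curve.y[3]) <= 2 * max(pooled, 0.01)

    def test_single_point_curve_equals_plain_cv(self):
        fm, y, _ = _planted(300)
        p = fm.shape[1]
        curve = error_vs_num_features(fm, y, [p], FAST_RF, seed=4)
        plain = cv_train_eval(fm, y, ModelSpec(n_estimators=50, select_k=p), seed=4)
        assert curve.y[0] == plain.mean_error

    def test_empty_k_grid_errors(self):
        fm, y, _ = _planted(100)
        with pytest.raises(ValueError):
            error_vs_num_features(fm, y, [], FAST_RF)

    def test_error_vs_dataset_size_flattens_to_noise_floor(self):
        fm, y, _ = _planted(3000, noise=0.15, seed=11)
        curve = error_vs_dataset_size(fm, y, [500, 1500, 3000], FAST_RF, seed=1)
        assert len(curve.x) == 3
        # larger samples approach the planted floor and never blow up
        assert curve.y[-1] < curve.y[0] + 2 * np.hypot(curve.yerr[0], curve.yerr[-1])
        assert curve.y[-1] >= 0.15 - 0.02  # never beats the planted Bayes floor

    def test_size_grid_full_equals_plain_cv(self):
        fm, y, _ = _planted(400)
        curve = error_vs_dataset_size(fm, y, [400], FAST_RF, seed=2)
        plain = cv_train_eval(fm, y, FAST_RF, seed=2)
        assert curve.y[0] == plain.mean_error

    def test_nested_subsamples_are_nested_and_stratified(self):
        _, y, _ = _planted(1000, seed=12)
        subs = stratified_nested_subsamples(y, [200, 600, 1000], seed=0)
        assert set(subs[200]) <= set(subs[600]) <= set(subs[1000])
        for n, idx in subs.items():
            assert len(idx) == n
            assert abs(y[idx].mean() - y.mean()) < 0.05


class TestImportanceAndChecks:
    def test_planted_feature_tops_every_run(self):
        rng = np.random.default_rng(13)
        n = 400
        y = rng.integers(0, 2, n)
        X = np.column_stack([
            y + 0.1 * rng.normal(size=n),
            rng.normal(size=(n, 9)).T.reshape(9, n).T,
        ])
        fm = FeatureMatrix.from_array(X, ["signal"] + [f"noise{j}" for j in range(9)])
        stab = gini_importance_stability(fm, y, ModelSpec(n_estimators=30), n_runs=3)
        for run in range(3):
            assert stab.top_feature(run) == "signal"
        assert stab.rank_agreement > 0.1

    def test_pure_noise_importances_unstable(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(200, 30))
        y = rng.integers(0, 2, 200)
        stab = gini_importance_stability(
            FeatureMatrix.from_array(X), y, ModelSpec(n_estimators=10), n_runs=3
        )
        assert abs(stab.rank_agreement) < 0.5

    def test_identical_seed_identical_importances(self):
        fm, y, _ = _planted(200)
        s1 = gini_importance_stability(fm, y, FAST_RF, n_runs=2, seeds=[5, 5])
        np.testing.assert_array_equal(s1.importances[0], s1.importances[1])

    def test_lasso_on_separable_and_agreement_with_rf(self):
        # low-dimensional planted rule: both model families learn it well
        X, y, info = planted_features(1500, n_informative=4, n_noise=12, seed=15)
        fm = FeatureMatrix.from_array(
            X, info + [f"noise_{j:02d}" for j in range(12)]
        )
        acc = lasso_logistic_check(fm, y, seed=0)
        assert acc > 0.9
        rf_acc = 1 - cv_train_eval(fm, y, FAST_RF, seed=0).mean_error
        assert abs(acc - rf_acc) < 0.1

    def test_lasso_subsample(self):
        fm, y, _ = _planted(600, seed=16)
        acc = lasso_logistic_check(fm, y, subsample_n=300, seed=1)
        assert 0.5 < acc <= 1.0


class TestRegressionAndPCA:
    def test_deterministic_target_near_zero_rmse(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(800, 4))
        target = 3.0 * X[:, 0]
        rmse = rf_regression_rmse(
            FeatureMatrix.from_array(X), target, seed=0,
            model_spec=ModelSpec(kind="rf_regressor", n_estimators=60),
        )
        assert rmse < 0.6  # small vs target sd = 3

    def test_constant_target_warns_zero(self):
        X = np.random.default_rng(0).normal(size=(50, 3))
        with pytest.warns(UserWarning):
            assert rf_regression_rmse(FeatureMatrix.from_array(X), np.ones(50)) == 0.0

    def test_irreducible_noise_floor(self):
        rng = np.random.default_rng(18)
        n = 3000
        X = rng.normal(size=(n, 3))
        target = 2.0 * X[:, 0] + rng.normal(scale=1.0, size=n)
        rmse = rf_regression_rmse(
            FeatureMatrix.from_array(X), target, seed=1,
            model_spec=ModelSpec(kind="rf_regressor", n_estimators=60),
        )
        assert 0.9 < rmse < 1.4  # approaches sigma=1 from above

    def test_pca_separated_and_overlapping_classes(self):
        rng = np.random.default_rng(19)
        n = 500
        y = rng.integers(0, 2, n)
        # the class shift spans several (hence mutually correlated) columns,
        # so it survives per-column standardization and dominates PC1
        X_sep = rng.normal(size=(n, 5))
        X_sep[:, :3] += np.where(y == 1, 6.0, -6.0)[:, None]
        proj = pca_projection(FeatureMatrix.from_array(X_sep), y)
        assert proj.centroid_separation(0) > 4
        X_same = rng.normal(size=(n, 5))
        proj2 = pca_projection(FeatureMatrix.from_array(X_same), y)
        assert proj2.centroid_separation(0) < 0.5

    def test_pca_sign_convention_reproducible(self):
        rng = np.random.default_rng(20)
        X = rng.normal(size=(100, 4))
        y = rng.integers(0, 2, 100)
        a = pca_projection(FeatureMatrix.from_array(X), y)
        b = pca_projection(FeatureMatrix.from_array(X), y)
        np.testing.assert_allclose(a.scores, b.scores)
        for comp in a.components:
            assert comp[np.argmax(np.abs(comp))] > 0
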