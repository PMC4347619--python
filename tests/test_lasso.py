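"""Unit and property tests for standardization and the L1-logistic solver."""

import numpy as np
import pytest

from omicstack.folds import make_inner_folds
from omicstack.lasso import (
    LassoLogisticModel,
    apply_standardization,
    fit_lambda_path,
    fit_lasso_logistic,
    fit_standardization,
    kkt_residuals,
    lambda_max,
    predict_posterior,
)
from omicstack.oracle import reference_lasso_objective_min

from conftest import random_logistic_instance


class TestStandardization:
    def test_hand_example(self):
        # column [1, 3]: center 2, second central moment ((-1)^2 + 1^2)/2 = 1
        params = fit_standardization(np.array([[1.0], [3.0]]))
        assert params.center[0] == pytest.approx(2.0)
        assert params.scale[0] == pytest.approx(1.0)

    def test_constant_column_flagged_and_zeroed(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        params = fit_standardization(X)
        assert params.constant[0] and not params.constant[1]
        assert params.scale[0] == 1.0
        Xs = apply_standardization(X, params)
        assert np.all(Xs[:, 0] == 0.0)

    def test_transformed_columns_have_unit_second_central_moment(self, rng):
        X = rng.standard_normal((37, 8)) * rng.uniform(0.1, 5, 8) + rng.normal(0, 3, 8)
        Xs = apply_standardization(X, fit_standardization(X))
        assert np.allclose(Xs.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(np.mean(Xs**2, axis=0), 1.0, atol=1e-12)

    def test_population_denominator_not_m_minus_1(self):
        X = np.array([[0.0], [2.0], [4.0]])
        params = fit_standardization(X)
        # population SD of {0,2,4} is sqrt(8/3), sample SD would be 2
        assert params.scale[0] == pytest.approx(np.sqrt(8.0 / 3.0))

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_standardization(np.empty((0, 3)))
        with pytest.raises(ValueError):
            fit_standardization(np.ones((1, 3)))


class TestFitLassoLogistic:
    def test_null_model_at_lambda_max(self, rng):
        X, y = random_logistic_instance(rng, 40, 12)
        Xs = apply_standardization(X, fit_standardization(X))
        lmax = lambda_max(Xs, y)
        for lam in (lmax, lmax * 1.5):
            model = fit_lasso_logistic(Xs, y, lam)
            assert model.n_selected == 0
            ybar = y.mean()
            assert model.intercept == pytest.approx(np.log(ybar / (1 - ybar)), abs=1e-6)

    def test_single_class_raises_with_context(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError, match="single class.*inv16 fold 2"):
            fit_lasso_logistic(X, np.ones(10), 0.1, context="inv16 fold 2")

    def test_objective_monotone_across_sweeps(self, rng):
        for _ in range(5):
            X, y = random_logistic_instance(rng, 30, 10)
            Xs = apply_standardization(X, fit_standardization(X))
            model = fit_lasso_logistic(Xs, y, 0.05)
            hist = np.array(model.objective_history)
            assert np.all(np.diff(hist) <= 1e-12)

    def test_kkt_conditions_at_convergence(self, rng):
        for _ in range(5):
            X, y = random_logistic_instance(rng, 50, 20)
            Xs = apply_standardization(X, fit_standardization(X))
            lam = 0.05
            model = fit_lasso_logistic(Xs, y, lam)
            scores = kkt_residuals(model, Xs, y)
            nz = model.nonzero_index
            zero = np.setdiff1d(np.arange(20), nz)
            assert np.all(scores[zero] <= lam + 1e-6)
            if len(nz):
                assert np.allclose(scores[nz], lam, atol=1e-6)

    def test_matches_convex_oracle_on_small_instances(self, rng):
        # objective equality against an independent general-purpose solver
        for _ in range(8):
            m, p = int(rng.integers(10, 31)), int(rng.integers(2, 7))
            X, y = random_logistic_instance(rng, m, p)
            Xs = apply_standardization(X, fit_standardization(X))
            lam = float(rng.uniform(0.005, 0.3))
            model = fit_lasso_logistic(Xs, y, lam)
            assert model.converged
            gap = model.objective_history[-1] - reference_lasso_objective_min(Xs, y, lam)
            assert gap < 1e-5

    def test_recovers_single_planted_column(self):
        # strong single informative column selected, noise columns zero
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((60, 10))
            eta = 3.0 * X[:, 4]
            y = (rng.random(60) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
            if y.min() == y.max():
                continue
            Xs = apply_standardization(X, fit_standardization(X))
            model = fit_lasso_logistic(Xs, y, 0.1)
            if model.coef[4] != 0 and np.count_nonzero(model.coef) <= 3:
                hits += 1
        assert hits >= 9

    def test_matches_sklearn_l1_solver(self, rng):
        # independent cross-check: liblinear on the same objective up to the
        # lambda = 1/(C*m) reparametrization
        from sklearn.linear_model import LogisticRegression

        X, y = random_logistic_instance(rng, 80, 10)
        Xs = apply_standardization(X, fit_standardization(X))
        lam = 0.03
        model = fit_lasso_logistic(Xs, y, lam)
        sk = LogisticRegression(
            penalty="l1", C=1.0 / (lam * len(y)), solver="liblinear", tol=1e-10,
            max_iter=10000,
        ).fit(Xs, y)

        def obj(b0, b):
            eta = b0 + Xs @ b
            return np.mean(np.logaddexp(0, eta) - y * eta) + lam * np.abs(b).sum()

        ours = obj(model.intercept, model.coef)
        theirs = obj(float(sk.intercept_[0]), sk.coef_[0])
        assert ours <= theirs + 1e-6


class TestPredictPosterior:
    def test_zero_model_gives_half(self):
        model = LassoLogisticModel(0.0, np.zeros(3), 0.1, None, ["a", "b", "c"])
        post = predict_posterior(model, np.random.default_rng(0).standard_normal((5, 3)))
        assert np.allclose(post, 0.5)

    def test_intercept_limits(self):
        X = np.zeros((2, 1))
        up = LassoLogisticModel(800.0, np.zeros(1), 0.0, None, ["f"])
        dn = LassoLogisticModel(-800.0, np.zeros(1), 0.0, None, ["f"])
        assert np.allclose(predict_posterior(up, X), 1.0)
        assert np.allclose(predict_posterior(dn, X), 0.0)

    def test_feature_alignment_by_id(self, rng):
        X, y = random_logistic_instance(rng, 40, 6)
        std = fit_standardization(X)
        Xs = apply_standardization(X, std)
        fids = [f"f{j}" for j in range(6)]
        model = fit_lasso_logistic(Xs, y, 0.02, feature_ids=fids, standardization=std)
        base = predict_posterior(model, X, fids)
        perm = [3, 1, 5, 0, 2, 4]
        permuted = predict_posterior(model, X[:, perm], [fids[j] for j in perm])
        assert np.allclose(base, permuted)

    def test_missing_feature_ids_raise(self):
        model = LassoLogisticModel(0.0, np.ones(2), 0.1, None, ["a", "b"])
        with pytest.raises(KeyError, match="b"):
            predict_posterior(model, np.zeros((3, 2)), ["a", "c"])


class TestLambdaPath:
    def test_first_grid_point_is_null_model(self, rng):
        X, y = random_logistic_instance(rng, 50, 15)
        path = fit_lambda_path(X, y, make_inner_folds(y, 5, 0), grid_size=20)
        assert path.models[0].n_selected == 0
        assert np.all(np.diff(path.grid) < 0)

    def test_sparsity_monotone_along_path(self, rng):
        X, y = random_logistic_instance(rng, 60, 12)
        path = fit_lambda_path(X, y, make_inner_folds(y, 5, 1), grid_size=25)
        nnz = [m.n_selected for m in path.models]
        # non-increasing in lambda == non-decreasing along the decreasing grid
        assert all(b >= a for a, b in zip(nnz, nnz[1:]))

    def test_pure_noise_selects_near_null(self):
        counts = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = rng.standard_normal((60, 80))
            y = (rng.random(60) < 0.4).astype(float)
            if y.min() == y.max():
                continue
            path = fit_lambda_path(X, y, make_inner_folds(y, 5, seed), grid_size=25)
            counts.append(path.selected_model.n_selected)
        assert np.median(counts) <= 2

    def test_signal_beats_null_deviance(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((80, 40))
        eta = 2.0 * X[:, :5].sum(axis=1)
        y = (rng.random(80) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        path = fit_lambda_path(X, y, make_inner_folds(y, 5, 2), grid_size=25)
        assert path.selected_index > 0  # selected lambda < lambda_max
        assert path.cv_deviance[path.selected_index] < path.null_deviance

    def test_degenerate_inner_fold_merged_with_warning(self):
        from omicstack.folds import FoldAssignment

        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 5))
        y = np.zeros(20)
        y[0] = y[1] = 1
        # both positives sit in fold 0, so holding out any other fold is fine
        # but holding out nothing: removing fold 0 leaves a single class
        fa = FoldAssignment(
            fold=np.array([0] * 7 + [1] * 7 + [2] * 6), k=3, seed=0, level="inner"
        )
        with pytest.warns(RuntimeWarning, match="merged"):
            path = fit_lambda_path(X, y, fa, grid_size=5)
        assert len(path.warnings_log) >= 1


class TestSerialization:
    def test_model_json_round_trip_predicts_identically(self, rng):
        X, y = random_logistic_instance(rng, 50, 8)
        std = fit_standardization(X)
        Xs = apply_standardization(X, std)
        fids = [f"g{j}" for j in range(8)]
        model = fit_lasso_logistic(Xs, y, 0.02, feature_ids=fids, standardization=std)
        clone = LassoLogisticModel.from_json_dict(model.to_json_dict())
        a = predict_posterior(model, X, fids)
        b = predict_posterior(clone, X, fids)
        assert np.allclose(a, b, atol=1e-15)
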