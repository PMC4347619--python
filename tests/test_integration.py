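"""Strategy mechanics: concatenation, the nearest-mean second layer, and
selected-feature accounting."""

import numpy as np
import pytest

from omicstack.datatypes import OmicsMatrix
from omicstack.folds import make_inner_folds
from omicstack.integration import (
    concat_features,
    count_selected_features,
    fit_nmc,
    nmc_score,
    train_strategy,
)


def _om(values, platform, prefix):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return OmicsMatrix(
        values, [f"S{i}" for i in range(n)], [f"{prefix}{j}" for j in range(p)], platform
    )


class TestConcat:
    def test_dimensionality_is_sum(self, rng):
        gep = _om(rng.standard_normal((4, 7)), "GEP", "g")
        dmp = _om(rng.standard_normal((4, 5)), "DMP", "m")
        em = concat_features(gep, dmp)
        assert em.n_features == 12
        assert (em.origins == "GEP").sum() == 7
        assert (em.origins == "DMP").sum() == 5

    def test_empty_second_matrix_is_identity(self, rng):
        gep = _om(rng.standard_normal((3, 4)), "GEP", "g")
        dmp = _om(np.empty((3, 0)), "DMP", "m")
        em = concat_features(gep, dmp)
        assert np.array_equal(em.matrix.values, gep.values)
        assert set(em.origins) == {"GEP"}

    def test_round_trip_by_origin(self, rng):
        gep = _om(rng.standard_normal((5, 3)), "GEP", "g")
        dmp = _om(rng.standard_normal((5, 4)), "DMP", "m")
        em = concat_features(gep, dmp)
        back_g = em.subset_by_origin("GEP")
        back_d = em.subset_by_origin("DMP")
        assert np.array_equal(back_g.values, gep.values)
        assert back_g.feature_ids == gep.feature_ids
        assert np.array_equal(back_d.values, dmp.values)

    def test_sample_mismatch_lists_difference(self, rng):
        gep = _om(rng.standard_normal((3, 2)), "GEP", "g")
        dmp = OmicsMatrix(
            rng.standard_normal((3, 2)), ["S0", "S1", "SX"], ["m0", "m1"], "DMP"
        )
        with pytest.raises(ValueError, match="SX"):
            concat_features(gep, dmp)


class TestNMC:
    def test_symmetric_corners_give_antidiagonal_boundary(self):
        pts = np.array([[1, 1], [1, 1], [0, 0], [0, 0]], dtype=float)
        y = np.array([1, 1, 0, 0])
        model = fit_nmc(pts, y)
        # boundary p_gep + p_dmp = 1: points on it score 0
        on = np.array([[0.5, 0.5], [0.2, 0.8], [1.0, 0.0]])
        scores, preds = nmc_score(model, on)
        assert np.allclose(scores, 0.0, atol=1e-12)
        assert np.all(preds == 1)  # tie goes to positive

    def test_hand_computed_means_and_vertical_boundary(self):
        pts = np.array([[0.8, 0.2], [0.6, 0.4], [0.2, 0.2], [0.4, 0.4]])
        y = np.array([1, 1, 0, 0])
        model = fit_nmc(pts, y)
        assert np.allclose(model.mean_positive, [0.7, 0.3])
        assert np.allclose(model.mean_negative, [0.3, 0.3])
        # bisector is p_gep = 0.5 (means share the second coordinate)
        scores, _ = nmc_score(model, np.array([[0.5, v] for v in (0.0, 0.3, 1.0)]))
        assert np.allclose(scores, 0.0, atol=1e-12)

    def test_translation_equivariance(self, rng):
        pts = rng.random((10, 2))
        y = (rng.random(10) < 0.5).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        shift = np.array([0.13, -0.27])
        a = fit_nmc(pts, y)
        b = fit_nmc(pts + shift, y)
        assert np.allclose(b.mean_positive, a.mean_positive + shift)
        assert np.allclose(b.mean_negative, a.mean_negative + shift)

    def test_score_at_positive_mean(self):
        model = fit_nmc(np.array([[0.9, 0.8], [0.1, 0.2]]), np.array([1, 0]))
        scores, preds = nmc_score(model, model.mean_positive[None, :])
        gap = ((model.mean_positive - model.mean_negative) ** 2).sum()
        assert scores[0] == pytest.approx(gap)
        assert preds[0] == 1

    def test_score_is_affine_so_roc_is_boundary_distance_roc(self, rng):
        # affine score: pairwise order equals order of signed boundary distance
        model = fit_nmc(rng.random((8, 2)), np.array([1, 1, 1, 1, 0, 0, 0, 0]))
        pts = rng.random((20, 2))
        scores, _ = nmc_score(model, pts)
        w = 2 * (model.mean_positive - model.mean_negative)
        b = (model.mean_negative @ model.mean_negative) - (
            model.mean_positive @ model.mean_positive
        )
        assert np.allclose(scores, pts @ w + b, atol=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            fit_nmc(np.random.default_rng(0).random((4, 2)), np.ones(4))


class TestTrainStrategyAndCounts:
    def _signal_data(self, seed=0, where="gep"):
        rng = np.random.default_rng(seed)
        n, p = 80, 40
        y = (rng.random(n) < 0.3).astype(float)
        if y.min() == y.max():
            y[0] = 1.0
        g = rng.standard_normal((n, p))
        d = rng.standard_normal((n, p))
        if where in ("gep", "both"):
            g[y == 1, :6] += 2.5
        if where in ("dmp", "both"):
            d[y == 1, :6] += 2.5
        return _om(g, "GEP", "g"), _om(d, "DMP", "m"), y

    def test_single_platform_counts_are_one_sided(self):
        gep, dmp, y = self._signal_data()
        inner = make_inner_folds(y, 5, 0)
        fit = train_strategy("gep", gep, dmp, y, inner, grid_size=12)
        counts = count_selected_features(fit)
        assert counts["DMP"] == 0 and counts["GEP"] > 0

    def test_early_counts_partition_total(self):
        gep, dmp, y = self._signal_data(where="both")
        inner = make_inner_folds(y, 5, 1)
        fit = train_strategy("early", gep, dmp, y, inner, grid_size=12)
        counts = count_selected_features(fit)
        assert counts["GEP"] + counts["DMP"] == fit.model.n_selected
        assert counts["GEP"] > 0 and counts["DMP"] > 0

    def test_early_standardization_unit_moment_for_all_origins(self):
        gep, dmp, y = self._signal_data(where="both")
        # different raw scales per platform
        gep = _om(gep.values * 100.0, "GEP", "g")
        inner = make_inner_folds(y, 5, 2)
        fit = train_strategy("early", gep, dmp, y, inner, grid_size=8)
        std = fit.model.standardization
        from omicstack.integration import concat_features

        em = concat_features(gep, dmp)
        Xs = (em.matrix.values - std.center) / std.scale
        assert np.allclose(np.mean(Xs**2, axis=0), 1.0, atol=1e-10)

    def test_late_boundary_vertical_when_only_gep_informative(self):
        slopes = []
        for seed in range(6):
            gep, dmp, y = self._signal_data(seed=seed, where="gep")
            inner = make_inner_folds(y, 5, seed)
            fit = train_strategy("late", gep, dmp, y, inner, grid_size=12)
            w = fit.second_layer.mean_positive - fit.second_layer.mean_negative
            # boundary normal w: vertical boundary means |w_gep| >> |w_dmp|
            slopes.append(abs(w[1]) / (abs(w[0]) + 1e-12))
        assert np.median(slopes) < 0.35

    def test_shared_platform_paths_reused_between_late_and_single(self):
        gep, dmp, y = self._signal_data(where="both")
        inner = make_inner_folds(y, 5, 3)
        cache = {}
        single = train_strategy("gep", gep, dmp, y, inner, grid_size=8, platform_paths=cache)
        late = train_strategy("late", gep, dmp, y, inner, grid_size=8, platform_paths=cache)
        assert late.first_layer_gep is single.model

    def test_out_of_fold_nmc_option_runs(self):
        gep, dmp, y = self._signal_data(where="both")
        inner = make_inner_folds(y, 5, 4)
        fit = train_strategy(
            "late", gep, dmp, y, inner, grid_size=8, nmc_posteriors="out_of_fold"
        )
        pts = fit.posterior_points(gep, dmp)
        assert np.all((pts >= 0) & (pts <= 1))
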