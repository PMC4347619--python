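"""Metric definitions, the permutation global test, and report aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicstack.metrics import (
    aggregate_report,
    confusion,
    f_score,
    global_test,
    roc_auc,
)
from omicstack.oracle import brute_force_auc


class TestFScore:
    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 0])
        assert f_score(y, np.array([0.9, 0.1, 0.8, 0.2])) == 1.0

    def test_hand_computed_two_thirds(self):
        # tp=2, fp=1, fn=1 -> precision = recall = 2/3 -> F = 2/3
        y = np.array([1, 1, 1, 0, 0])
        post = np.array([0.9, 0.8, 0.1, 0.7, 0.2])
        assert f_score(y, post) == pytest.approx(2 / 3)

    def test_no_predicted_positives_is_zero(self):
        y = np.array([1, 1, 0])
        assert f_score(y, np.array([0.1, 0.2, 0.3])) == 0.0

    def test_threshold_is_inclusive_at_half(self):
        y = np.array([1, 0])
        # posterior exactly 0.5 counts as a positive call
        assert f_score(y, np.array([0.5, 0.0])) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            f_score(np.array([]), np.array([]))

    def test_confusion_totals(self):
        y = np.array([1, 1, 0, 0, 1])
        pred = np.array([1, 0, 1, 0, 1])
        c = confusion(y, pred)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 1)
        assert c.total == 5

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 1), st.floats(0, 1)), min_size=2, max_size=30))
    def test_f_bounded_and_diagonal_iff_one(self, pairs):
        y = np.array([p[0] for p in pairs])
        post = np.array([p[1] for p in pairs])
        f = f_score(y, post)
        assert 0.0 <= f <= 1.0
        pred = (post >= 0.5).astype(int)
        if f == 1.0:
            assert np.array_equal(pred, y)


class TestAUC:
    def test_separated_scores(self):
        assert roc_auc(np.array([1, 1, 0, 0]), np.array([3.0, 2.0, 1.0, 0.0])) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc(np.array([1, 0, 1, 0]), np.zeros(4)) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(4), np.arange(4.0))

    def test_equals_brute_force_pair_counting(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 13))
            y = (rng.random(n) < 0.5).astype(int)
            if y.min() == y.max():
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert roc_auc(y, scores) == pytest.approx(brute_force_auc(y, scores), abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(
        st.lists(st.tuples(st.integers(0, 1), st.floats(-5, 5)), min_size=4, max_size=25),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    def test_invariant_under_strictly_monotone_transforms(self, pairs, kind):
        y = np.array([p[0] for p in pairs])
        if y.min() == y.max():
            return
        # coarse grid keeps the transforms strictly monotone in floating point
        s = np.round(np.array([p[1] for p in pairs]), 3)
        t = {"exp": np.exp, "cube": lambda v: v**3, "affine": lambda v: 2.5 * v + 7}[kind](s)
        assert roc_auc(y, t) == pytest.approx(roc_auc(y, s), abs=1e-12)


class TestGlobalTest:
    def test_all_zero_features(self):
        y = np.array([1.0, 0, 1, 0])
        res = global_test(np.zeros((4, 3)), y, n_permutations=200, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_floor_at_one_over_b_plus_one(self):
        rng = np.random.default_rng(0)
        n = 40
        y = (np.arange(n) < 15).astype(float)
        yc = y - y.mean()
        X = np.column_stack([yc * 5, rng.standard_normal(n) * 0.01])
        res = global_test(X, y, n_permutations=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)

    def test_column_equal_to_centered_y_maximizes_q(self):
        # among unit-norm single columns, X = c*(y - ybar) maximizes
        # (X^T(y-ybar))^2 by Cauchy-Schwarz
        rng = np.random.default_rng(2)
        n = 30
        y = (rng.random(n) < 0.4).astype(float)
        yc = y - y.mean()
        best = yc / np.linalg.norm(yc)
        q_best = float(((best @ yc) ** 2))
        for _ in range(50):
            v = rng.standard_normal(n)
            v /= np.linalg.norm(v)
            assert (v @ yc) ** 2 <= q_best + 1e-12

    def test_matches_loop_oracle_in_distribution(self):
        # vectorized block permutation vs plain loop: p-values agree closely
        from omicstack.oracle import brute_force_global_test_p

        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 5))
        y = (rng.random(30) < 0.5).astype(float)
        a = global_test(X, y, n_permutations=4000, seed=7).p_value
        b = brute_force_global_test_p(X, y, 4000, seed=8)
        assert abs(a - b) < 0.04

    def test_warning_for_few_permutations(self):
        rng = np.random.default_rng(4)
        with pytest.warns(RuntimeWarning):
            global_test(rng.standard_normal((10, 2)), np.array([1.0, 0] * 5), 50, 0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            global_test(np.zeros((4, 2)), np.ones(4), 200, 0)


class TestAggregation:
    def _result(self):
        from omicstack.dlcv import OneVsAllTask, run_dlcv
        from omicstack.datatypes import OmicsMatrix

        rng = np.random.default_rng(0)
        n, p = 50, 20
        y = (rng.random(n) < 0.4).astype(float)
        X = rng.standard_normal((n, p))
        X[y == 1, :4] += 2.0
        sids = [f"S{i}" for i in range(n)]
        gep = OmicsMatrix(X, sids, [f"g{j}" for j in range(p)], "GEP")
        dmp = OmicsMatrix(rng.standard_normal((n, p)), sids, [f"m{j}" for j in range(p)], "DMP")
        return run_dlcv(
            [OneVsAllTask("t", y)], gep, dmp, ["gep", "dmp"], seed=0, grid_size=8
        )

    def test_means_recompute_from_fold_detail(self):
        rep = aggregate_report(self._result())
        for e in rep.entries:
            vals = [v for v in e.fold_f if v is not None]
            assert e.mean_f == pytest.approx(np.mean(vals))
            aucs = [v for v in e.fold_auc if v is not None]
            assert e.mean_auc == pytest.approx(np.mean(aucs))

    def test_json_round_trip_self_consistent(self):
        rep = aggregate_report(self._result())
        from omicstack.metrics import StrategyReport

        clone = StrategyReport.from_json(rep.to_json())
        assert clone.to_json() == rep.to_json()
        for e in clone.entries:
            vals = [v for v in e.fold_f if v is not None]
            assert e.mean_f == pytest.approx(np.mean(vals))

    def test_mean_over_valid_folds_only(self):
        from omicstack.metrics import TaskStrategyEntry, _mean_or_none

        vals = [0.5, None, 0.7, 0.9, None]
        assert _mean_or_none(vals) == pytest.approx(0.7)

    def test_constant_proportions_give_correlation_one(self):
        from omicstack.metrics import _corr

        assert _corr([3, 3, 3], [5, 5, 5]) == 1.0
        assert _corr([1, 2, 3], [2, 4, 6.0]) == pytest.approx(1.0)
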