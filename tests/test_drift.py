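import numpy as np
import pytest
from sklearn.svm import SVC

import driftseize.drift as drift_mod
from driftseize.classify import SVMConfig
from driftseize.drift import (
    WeightedEnsemble,
    blw_select,
    dwe_build,
    dwe_predict,
    dwe_weigh,
    loo_estimate,
    sbr_angle,
    sbr_select,
)

from conftest import make_training_problem


class TestLooEstimate:
    def test_wide_margin_both_modes_zero(self, rng):
        X = np.vstack([rng.normal(-6, 0.2, (20, 2)), rng.normal(6, 0.2, (20, 2))])
        y = np.r_[np.zeros(20, int), np.ones(20, int)]
        model = SVC(kernel="linear", C=1.0).fit(X, y)
        assert loo_estimate(model, X, y, "xi_alpha") == 0.0
        assert loo_estimate(model, X, y, "exact") == 0.0

    def test_xi_alpha_upper_bounds_exact(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 41))
            X = rng.standard_normal((n, 3))
            y = (rng.random(n) < 0.5).astype(int)
            if len(np.unique(y)) < 2:
                y[0] = 1 - y[0]
            model = SVC(kernel="linear", C=1.0).fit(X, y)
            xa = loo_estimate(model, X, y, "xi_alpha")
            ex = loo_estimate(model, X, y, "exact")
            assert xa >= ex - 1e-12

    def test_untrained_model_rejected(self):
        with pytest.raises(ValueError, match="not a trained"):
            loo_estimate(SVC(), np.zeros((2, 2)), np.array([0, 1]))

    def test_exact_undefined_for_single_row(self, rng):
        X = np.vstack([rng.normal(-2, 0.1, (5, 2)), rng.normal(2, 0.1, (5, 2))])
        y = np.r_[np.zeros(5, int), np.ones(5, int)]
        model = SVC(kernel="linear", C=1.0).fit(X, y)
        with pytest.raises(ValueError, match="n < 2"):
            loo_estimate(model, X[:1], y[:1], "exact")


class TestSbrAngle:
    @pytest.mark.parametrize(
        "w1,w2,expected",
        [
            ([1, 0], [0, 1], 90.0),
            ([1, 1], [1, 0], 45.0),
            ([1, 0], [-1, 0], 180.0),
            ([2, 3], [2, 3], 0.0),
        ],
    )
    def test_analytic_angles(self, w1, w2, expected):
        assert sbr_angle(np.array(w1, float), np.array(w2, float)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_symmetry_and_scale_invariance(self, rng):
        for _ in range(100):
            w1, w2 = rng.standard_normal((2, 6))
            a = sbr_angle(w1, w2)
            assert a == pytest.approx(sbr_angle(w2, w1), abs=1e-9)
            assert a == pytest.approx(sbr_angle(3.7 * w1, w2), abs=1e-7)
            assert 0.0 <= a <= 180.0

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            sbr_angle(np.zeros(3), np.ones(3))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            sbr_angle(np.ones(2), np.ones(3))


class TestBlwSelect:
    def test_selected_estimate_is_minimum_of_table(self):
        Z, y, t, _, _, _ = make_training_problem(seed=0)
        sel = blw_select(Z, y, t, cfg=SVMConfig(cost=1.0))
        evaluated = sel.table["loo"].dropna()
        assert sel.loo == pytest.approx(evaluated.min())
        # smallest window among ties
        assert sel.window_hours == int(
            sel.table.loc[sel.table["loo"].idxmin(), "window_hours"]
        )

    def test_early_stop_patience_contract(self, rng, monkeypatch):
        # flat estimates: window w=13 must never be evaluated once the best
        # (w=1) has not improved over 12 hours of growth
        monkeypatch.setattr(drift_mod, "loo_estimate", lambda *a, **k: 0.5)
        n = 20 * 60  # 20 hours of 1-minute rows
        t = np.arange(n) * 60.0
        y = (np.arange(n) % 2).astype(int)
        Z = rng.standard_normal((n, 3))
        sel = blw_select(Z, y, t, cfg=SVMConfig(cost=1.0))
        assert sel.window_hours == 1
        assert sel.table["window_hours"].max() == 12.0

    def test_no_trainable_window_rejected(self, rng):
        n = 240
        t = np.arange(n) * 60.0
        with pytest.raises(ValueError, match="both classes"):
            blw_select(rng.standard_normal((n, 2)), np.zeros(n, int), t)

    def test_stationary_prefers_large_windows(self):
        hits = 0
        for seed in range(10):
            Z, y, t, _, _, _ = make_training_problem(seed=seed)
            sel = blw_select(Z, y, t, cfg=SVMConfig(cost=1.0))
            hits += sel.window_hours >= len(sel.table) - 2
        assert hits >= 6

    def test_abrupt_inversion_shrinks_window(self):
        hits = 0
        for seed in range(10):
            Z, y, t, _, _, _ = make_training_problem(seed=seed, drift=("abrupt", 2))
            sel = blw_select(Z, y, t, cfg=SVMConfig(cost=1.0))
            hits += sel.window_hours <= 6
        assert hits >= 8


class TestSbrSelect:
    def test_singleton_reference_has_zero_angle(self):
        _, _, _, zb, _, _ = make_training_problem(seed=1, n_select=10)
        sel = sbr_select(zb, cfg=SVMConfig(cost=1.0))
        table = {tuple(r["subset"]): r["angle_degrees"] for _, r in sel.table.iterrows()}
        assert table[(2,)] == pytest.approx(0.0, abs=1e-9)
        assert len(table) == 7  # all non-empty subsets of 3 seizures

    def test_stationary_selects_full_set(self):
        hits = 0
        for seed in range(10):
            _, _, _, zb, _, _ = make_training_problem(seed=seed, n_select=10)
            sel = sbr_select(zb, cfg=SVMConfig(cost=1.0))
            hits += sel.subset == (0, 1, 2)
        assert hits >= 6

    def test_inverted_first_seizure_excluded(self):
        hits = 0
        for seed in range(10):
            _, _, _, zb, _, _ = make_training_problem(
                seed=seed, drift=("abrupt", 1), n_select=10
            )
            sel = sbr_select(zb, cfg=SVMConfig(cost=1.0))
            hits += 0 not in sel.subset
        assert hits >= 8

    def test_needs_two_batches(self):
        _, _, _, zb, _, _ = make_training_problem(seed=0, n_select=5)
        with pytest.raises(ValueError, match="at least 2"):
            sbr_select(zb[:1])


class _StubModel:
    def __init__(self, outputs):
        self.outputs = np.asarray(outputs, dtype=int)

    def predict(self, rows):
        return self.outputs[: len(rows)]


class TestDwe:
    def test_partition_count_and_conservation(self):
        Z, y, t, _, _, _ = make_training_problem(seed=2)
        ens = dwe_build(Z, y, t, cfg=SVMConfig(cost=1.0))
        span_h = (t.max() - t.min()) / 3600.0
        assert 1 <= len(ens.models) <= int(np.ceil(span_h))
        # periods are disjoint 1-hour intervals
        for (lo1, hi1), (lo2, hi2) in zip(ens.periods, ens.periods[1:]):
            assert hi2 <= lo1 and hi1 - lo1 == pytest.approx(3600.0)

    def test_weights_proportional_to_accuracy(self):
        concept_y = np.r_[np.zeros(10, int), np.ones(10, int)]
        rows = np.zeros((20, 1))
        # accuracies: model A 0.9 (18/20), model B 0.6 (12/20)
        pred_a = concept_y.copy()
        pred_a[:2] = 1 - pred_a[:2]
        pred_b = concept_y.copy()
        pred_b[:8] = 1 - pred_b[:8]
        ens = WeightedEnsemble(models=[_StubModel(pred_a), _StubModel(pred_b)], periods=[(0, 1), (1, 2)])
        w = dwe_weigh(ens, rows, concept_y)
        np.testing.assert_allclose(w, [0.6, 0.4])

    def test_zero_accuracy_model_gets_zero_weight(self):
        concept_y = np.ones(10, int)
        ens = WeightedEnsemble(
            models=[_StubModel(np.ones(10, int)), _StubModel(np.zeros(10, int))],
            periods=[(0, 1), (1, 2)],
        )
        w = dwe_weigh(ens, np.zeros((10, 1)), concept_y)
        np.testing.assert_allclose(w, [1.0, 0.0])

    def test_all_zero_accuracies_fall_back_to_uniform(self):
        ens = WeightedEnsemble(
            models=[_StubModel(np.zeros(5, int))] * 3, periods=[(0, 1)] * 3
        )
        w = dwe_weigh(ens, np.zeros((5, 1)), np.ones(5, int))
        np.testing.assert_allclose(w, 1 / 3)

    def test_degenerate_weight_on_first_model(self):
        ens = WeightedEnsemble(
            models=[_StubModel(np.array([1, 0, 1])), _StubModel(np.array([0, 1, 0]))],
            periods=[(0, 1), (1, 2)],
        )
        out = dwe_predict(ens, np.zeros((3, 1)), weights=np.array([1.0, 0.0]))
        np.testing.assert_array_equal(out, [1, 0, 1])

    def test_exact_half_vote_predicts_preictal(self):
        ens = WeightedEnsemble(
            models=[_StubModel(np.ones(2, int)), _StubModel(np.zeros(2, int))],
            periods=[(0, 1), (1, 2)],
        )
        out = dwe_predict(ens, np.zeros((2, 1)), weights=np.array([0.5, 0.5]))
        np.testing.assert_array_equal(out, [1, 1])

    def test_matches_brute_force_weighted_vote(self, rng):
        # all 2^n prediction patterns for n <= 4 models
        for n_models in (2, 3, 4):
            weights = rng.random(n_models)
            weights /= weights.sum()
            for pattern in range(2**n_models):
                votes = [(pattern >> i) & 1 for i in range(n_models)]
                ens = WeightedEnsemble(
                    models=[_StubModel(np.array([v])) for v in votes],
                    periods=[(i, i + 1) for i in range(n_models)],
                )
                got = dwe_predict(ens, np.zeros((1, 1)), weights=weights)[0]
                expected = int(sum(w * v for w, v in zip(weights, votes)) >= 0.5 - 1e-12)
                assert got == expected

    def test_empty_concept_window_rejected(self):
        ens = WeightedEnsemble(models=[_StubModel(np.ones(1, int))], periods=[(0, 1)])
        with pytest.raises(ValueError, match="empty"):
            dwe_weigh(ens, np.zeros((0, 1)), np.zeros(0, int))

    def test_unnormalised_weights_rejected(self):
        ens = WeightedEnsemble(models=[_StubModel(np.ones(1, int))], periods=[(0, 1)])
        with pytest.raises(ValueError, match="sum to 1"):
            dwe_predict(ens, np.zeros((1, 1)), weights=np.array([0.7]))
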