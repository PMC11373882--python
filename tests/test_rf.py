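"""Kernel response-field fitting, PRESS cross-validation, model comparison."""

import numpy as np
import pytest
from sklearn.base import clone

import gazecode as gc
from gazecode import frames
from gazecode.rf import FitConfig, KernelResponseField, TGContinuumLocalizer
from conftest import visual_rates


def brute_force_loo(positions, rates, h):
    """Independent leave-one-out oracle: refit from scratch per held-out trial."""
    n = len(rates)
    out = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        d2 = np.sum((positions[mask] - positions[i]) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * h * h))
        out[i] = rates[i] - (w @ rates[mask]) / w.sum()
    return out


class TestKernelPrediction:
    def test_single_training_point_returns_its_rate(self):
        assert gc.kernel_fit_predict(np.array([[3.0, 4.0]]), np.array([17.0]), np.array([0.0, 0.0]), 5.0) == pytest.approx(17.0)

    def test_equidistant_points_average(self):
        X = np.array([[-2.0, 0.0], [2.0, 0.0]])
        assert gc.kernel_fit_predict(X, np.array([10.0, 30.0]), np.array([0.0, 0.0]), 4.0) == pytest.approx(20.0)

    def test_hand_computed_weighted_mean(self):
        # weights 1, e^{-1/2}, e^{-2} for points 0, 4, 8 deg away at h = 4
        X = np.array([[0.0, 0.0], [4.0, 0.0], [8.0, 0.0]])
        v = gc.kernel_fit_predict(X, np.array([0.0, 10.0, 20.0]), np.array([0.0, 0.0]), 4.0)
        assert v == pytest.approx(5.0359858618, abs=1e-9)


class TestPressResiduals:
    def test_constant_rates_give_zero_residuals(self, rng):
        P = rng.uniform(-10, 10, size=(12, 2))
        res = gc.press_residuals(P, np.full(12, 7.5), h=5.0)
        assert np.allclose(res, 0.0)

    def test_two_trials_cross_predict_each_other(self):
        P = np.array([[0.0, 0.0], [5.0, 0.0]])
        res = gc.press_residuals(P, np.array([3.0, 11.0]), h=4.0)
        assert res == pytest.approx([-8.0, 8.0])

    @pytest.mark.parametrize("n,h", [(5, 3.0), (15, 6.0), (20, 12.0)])
    def test_matches_brute_force_oracle(self, rng, n, h):
        P = rng.uniform(-15, 15, size=(n, 2))
        r = rng.uniform(0, 100, size=n)
        assert np.allclose(gc.press_residuals(P, r, h), brute_force_loo(P, r, h), atol=1e-9)

    def test_mean_press_invariant_to_reorder_and_translation(self, rng):
        P = rng.uniform(-15, 15, size=(20, 2))
        r = rng.uniform(0, 50, size=20)
        base = np.mean(gc.press_residuals(P, r, 5.0) ** 2)
        perm = rng.permutation(20)
        assert np.mean(gc.press_residuals(P[perm], r[perm], 5.0) ** 2) == pytest.approx(base)
        assert np.mean(gc.press_residuals(P + [120.0, -40.0], r, 5.0) ** 2) == pytest.approx(base)


class TestBandwidthSelection:
    def test_constant_rates_tie_resolves_to_smallest_bandwidth(self, rng):
        P = rng.uniform(-10, 10, size=(10, 2))
        fr = gc.fit_model(P, np.full(10, 4.0))
        assert fr.bandwidth == 2.0
        assert fr.mean_press == pytest.approx(0.0, abs=1e-18)

    def test_single_bandwidth_grid_is_returned(self, rng):
        P = rng.uniform(-10, 10, size=(10, 2))
        fr = gc.fit_model(P, rng.uniform(0, 10, 10), FitConfig(bandwidths=np.array([7.0])))
        assert fr.bandwidth == 7.0

    def test_selected_bandwidth_matches_exhaustive_search(self, rng):
        P = rng.uniform(-15, 15, size=(60, 2))
        r = 50 * np.exp(-np.sum((P - [3, 2]) ** 2, axis=1) / 50.0) + rng.normal(0, 3, 60)
        cfg = FitConfig()
        fr = gc.fit_model(P, r, cfg)
        exhaustive = [np.mean(gc.press_residuals(P, r, h) ** 2) for h in cfg.bandwidths]
        assert fr.bandwidth == cfg.bandwidths[int(np.argmin(exhaustive))]
        assert fr.mean_press == pytest.approx(min(exhaustive))


class TestSklearnContract:
    def test_get_set_params_and_clone(self):
        est = KernelResponseField(bandwidth=5.0)
        assert clone(est).get_params()["bandwidth"] == 5.0
        loc = TGContinuumLocalizer()
        assert "alpha_grid" in loc.get_params()

    def test_fitted_attributes_and_predict(self, rng):
        X = rng.uniform(-10, 10, size=(30, 2))
        y = 40 * np.exp(-np.sum(X**2, axis=1) / 60.0)
        est = KernelResponseField().fit(X, y)
        assert est.bandwidth_ in gc.rf.default_bandwidths()
        assert est.press_residuals_.shape == (30,)
        pred = est.predict(np.array([[0.0, 0.0]]))
        assert 20 < pred[0] <= 41


class TestBrownForsythe:
    def test_identical_groups_degenerate(self):
        assert gc.brown_forsythe([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])[1] == pytest.approx(1.0)

    def test_zero_spread_groups_convention(self):
        stat, p = gc.brown_forsythe([1, 1, 1, 1], [5, 5, 5, 5])
        assert (stat, p) == (0.0, 1.0)

    def test_matches_textbook_one_way_f_on_median_deviations(self):
        a = np.array([12.0, 7.0, 3.0, 9.5, 14.0, 6.0])
        b = np.array([1.0, 2.0, 1.5, 2.5, 1.8])
        za = np.abs(a - np.median(a))
        zb = np.abs(b - np.median(b))
        # one-way F on the deviations, computed from first principles
        z = np.concatenate([za, zb])
        k, N = 2, len(z)
        ssb = len(za) * (za.mean() - z.mean()) ** 2 + len(zb) * (zb.mean() - z.mean()) ** 2
        ssw = np.sum((za - za.mean()) ** 2) + np.sum((zb - zb.mean()) ** 2)
        F = (ssb / (k - 1)) / (ssw / (N - k))
        stat, _ = gc.brown_forsythe(a, b)
        assert stat == pytest.approx(F)


class TestModelComparison:
    def test_degenerate_geometry_yields_no_tg_elimination(self):
        cfg = gc.TaskConfig(seed=4, endpoint_noise_sd=0.0, shift_attraction=0.0)
        unit = gc.UnitSpec(unit_id="u0", site_id="s0", coding_alpha=0.0, rf_center=(4.0, 3.0))
        s = gc.generate_session(cfg, units=[unit], n_trials_per_target=5)
        rates = visual_rates(s, "u0")
        mc = gc.compare_models(frames.model_positions(s.trials), rates)
        for t_m, g_m in (("Te", "Ge"), ("Ts", "Gs"), ("Th", "Gh")):
            assert mc.mean_press[t_m] == pytest.approx(mc.mean_press[g_m], rel=1e-9)
        assert not mc.eliminated["Ge" if mc.best_label == "Te" else "Te"]

    def test_best_model_p_value_is_one(self, rng):
        P = {m: rng.uniform(-10, 10, size=(20, 2)) for m in ("Te", "Ge")}
        r = rng.uniform(0, 50, 20)
        mc = gc.compare_models(P, r)
        assert mc.p_values[mc.best_label] == 1.0


class TestContinuumLocalizer:
    def test_indeterminate_when_target_equals_gaze(self, rng):
        te = rng.uniform(-10, 10, size=(20, 2))
        r = rng.uniform(0, 50, 20)
        cf = gc.fit_tg_continuum(te, te.copy(), r)
        assert cf.indeterminate
        assert cf.alpha == 0.0

    def test_profile_covers_grid_and_contains_minimum(self, rng):
        te = rng.uniform(-10, 10, size=(40, 2))
        ge = te + rng.normal(0, 4, size=(40, 2))
        r = 60 * np.exp(-np.sum((te - [2, 2]) ** 2, axis=1) / 40.0) + rng.normal(0, 2, 40)
        cf = gc.fit_tg_continuum(te, ge, r)
        assert len(cf.press_profile) == len(cf.alpha_grid)
        assert cf.mean_press == pytest.approx(cf.press_profile.min())
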