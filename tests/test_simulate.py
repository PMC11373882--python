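"""Synthetic gaze-session generator: behavior, spiking, waveforms, traces."""

import numpy as np
import pytest
from scipy import stats

import gazecode as gc
from gazecode.simulate import ConfigError, sample_units
from conftest import make_trials


class TestBehavior:
    def test_fixed_seed_is_bit_identical(self):
        a = gc.generate_session(gc.TaskConfig(seed=1), n_units=2, n_trials_per_target=3)
        b = gc.generate_session(gc.TaskConfig(seed=1), n_units=2, n_trials_per_target=3)
        assert a.trials.equals(b.trials)
        assert a.spikes.equals(b.spikes)
        for uid in a.waveforms:
            assert np.array_equal(a.waveforms[uid].samples, b.waveforms[uid].samples)

    def test_no_shift_config_keeps_landmark_and_virtual_target(self):
        s = gc.generate_session(gc.TaskConfig(seed=2, p_shift=0.0), n_units=1, n_trials_per_target=3)
        assert np.allclose(s.trials["land_x"], s.trials["land_shift_x"])
        assert np.allclose(s.trials["vtarg_x"], s.trials["targ_x"])
        assert np.allclose(s.trials["vtarg_y"], s.trials["targ_y"])
        assert not s.trials["is_shift"].any()

    def test_trial_count_and_shift_fraction_within_binomial_bounds(self):
        s = gc.generate_session(gc.TaskConfig(seed=3), n_units=1, n_trials_per_target=10)
        assert len(s.trials) == 160
        k = int(s.trials["is_shift"].sum())
        lo = stats.binom.ppf(0.005, 160, 0.9)
        hi = stats.binom.ppf(0.995, 160, 0.9)
        assert lo <= k <= hi

    def test_event_times_are_ordered(self, demo_session):
        t = demo_session.trials
        assert (t["t_target_on"] < t["t_mask_on"]).all()
        assert (t["t_mask_on"] < t["t_mask_off"]).all()
        assert (t["t_mask_off"] < t["t_go"]).all()
        assert (t["t_go"] <= t["t_sacc_on"]).all()
        assert (t["t_sacc_on"] < t["t_sacc_off"]).all()

    def test_additive_frame_invariants_hold(self, demo_session):
        t = demo_session.trials
        assert np.allclose(t["fix_x"], t["head0_x"] + t["eye0_x"])
        assert np.allclose(t["gaze_x"], t["head1_x"] + t["eye1_x"])
        assert np.allclose(t["vtarg_x"], t["targ_x"] + t["land_shift_x"] - t["land_x"])

    def test_zero_noise_no_attraction_gaze_hits_target(self):
        cfg = gc.TaskConfig(seed=4, endpoint_noise_sd=0.0, shift_attraction=0.0)
        s = gc.generate_session(cfg, n_units=1, n_trials_per_target=3)
        assert np.allclose(s.trials["gaze_x"], s.trials["targ_x"])
        assert np.allclose(s.trials["gaze_y"], s.trials["targ_y"])

    def test_target_gaze_correlation_exceeds_regime_floor(self):
        unit = gc.UnitSpec(unit_id="u0", site_id="s0", baseline_rate=0.0,
                           visual_gain=0.0, delay_gain=0.0, motor_gain=0.0)
        s = gc.generate_session(gc.TaskConfig(seed=5), units=[unit], n_trials_per_target=70)
        assert len(s.trials) >= 1000
        for ax in ("x", "y"):
            r = np.corrcoef(s.trials[f"targ_{ax}"], s.trials[f"gaze_{ax}"])[0, 1]
            assert r > 0.8

    def test_shift_directions_uniform_by_chi_square(self):
        unit = gc.UnitSpec(unit_id="u0", site_id="s0", baseline_rate=0.0,
                           visual_gain=0.0, delay_gain=0.0, motor_gain=0.0)
        s = gc.generate_session(gc.TaskConfig(seed=6), units=[unit], n_trials_per_target=70)
        dirs = s.trials.loc[s.trials["is_shift"], "shift_dir"].to_numpy()
        assert len(dirs) >= 800
        counts = np.bincount(dirs, minlength=8)
        chi2 = np.sum((counts - len(dirs) / 8.0) ** 2 / (len(dirs) / 8.0))
        assert chi2 < stats.chi2.ppf(0.99, df=7)

    def test_invalid_config_names_field(self):
        with pytest.raises(ConfigError, match="p_shift"):
            gc.generate_session(gc.TaskConfig(seed=0, p_shift=1.5), n_units=1)


class TestGazeEndpoint:
    def test_noise_free_no_attraction_returns_target(self, rng):
        G = gc.sample_gaze_endpoint([3.0, 4.0], [10.0, 4.0], [14.0, 4.0], 0.0, 0.0, rng)
        assert G == pytest.approx([3.0, 4.0])

    def test_full_attraction_inherits_whole_shift(self, rng):
        G = gc.sample_gaze_endpoint([3.0, 4.0], [10.0, 4.0], [18.0, 4.0], 1.0, 0.0, rng)
        assert G == pytest.approx([11.0, 4.0])

    def test_monte_carlo_mean_matches_partial_attraction(self, rng):
        shift = np.array([8.0, 0.0])
        draws = np.array([
            gc.sample_gaze_endpoint([0.0, 0.0], [11.0, 0.0], [11.0, 0.0] + shift, 0.3, 1.5, rng)
            for _ in range(10_000)
        ])
        se = 1.5 / np.sqrt(10_000)
        assert np.all(np.abs(draws.mean(axis=0) - 0.3 * shift) < 3 * se)


class TestSimulateUnit:
    def _trial(self):
        return make_trials([dict(targ_x=5.0, targ_y=5.0, gaze_x=5.0, gaze_y=5.0)]).iloc[0]

    def test_silent_unit_produces_empty_train(self, rng):
        u = gc.UnitSpec(unit_id="u", site_id="s", baseline_rate=0.0,
                        visual_gain=0.0, delay_gain=0.0, motor_gain=0.0)
        assert len(gc.simulate_unit(u, self._trial(), rng).spike_times) == 0

    def test_poisson_baseline_mean_count(self, rng):
        u = gc.UnitSpec(unit_id="u", site_id="s", baseline_rate=20.0,
                        visual_gain=0.0, delay_gain=0.0, motor_gain=0.0)
        trial = self._trial()
        lam = 20.0 * trial.t_end / 1000.0
        counts = [len(gc.simulate_unit(u, trial, rng).spike_times) for _ in range(400)]
        assert abs(np.mean(counts) - lam) < 3 * np.sqrt(lam / 400)

    def test_closed_field_prefers_response_field_center(self, rng):
        u = gc.UnitSpec(unit_id="u", site_id="s", coding_alpha=0.0, rf_center=(6.0, 0.0),
                        rf_sigma=5.0, baseline_rate=2.0, visual_gain=120.0,
                        delay_gain=0.0, motor_gain=0.0)
        at_center = make_trials([dict(targ_x=6.0, gaze_x=6.0)]).iloc[0]
        displaced = make_trials([dict(targ_x=21.0, gaze_x=21.0)]).iloc[0]  # 3 sigma away
        def mean_rate(trial):
            return np.mean([
                gc.epoch_rate(gc.simulate_unit(u, trial, rng).spike_times, (80.0, 180.0), trial.t_target_on)
                for _ in range(100)
            ])
        assert mean_rate(at_center) > mean_rate(displaced)

    def test_spike_times_sorted_within_trial_span(self, demo_session):
        g = demo_session.spikes.groupby(["unit_id", "trial_id"])["t_ms"]
        for (_, tid), times in g:
            arr = times.to_numpy()
            assert np.all(np.diff(arr) >= 0)
            t_end = float(demo_session.trials.loc[demo_session.trials.trial_id == tid, "t_end"].iloc[0])
            assert arr.min() >= 0 and arr.max() <= t_end


class TestWaveformsAndTraces:
    def test_fixed_seed_waveform_identical(self):
        a = gc.generate_waveform("RS", 9)
        b = gc.generate_waveform("RS", 9)
        assert np.array_equal(a.samples, b.samples)

    def test_fs_width_at_most_250us(self):
        for seed in range(5):
            w = gc.generate_waveform("FS", seed)
            tr = int(np.argmin(w.samples))
            pk = tr + 1 + int(np.argmax(w.samples[tr + 1:]))
            assert (pk - tr) * w.dt_us <= 250.0

    def test_empty_noiseless_trace_is_zero(self):
        tr = gc.generate_raw_trace([], 100.0, noise_sd=0.0, fs=20000.0)
        assert np.all(tr.samples == 0)

    def test_single_strong_spike_detected_once(self, rng):
        # short trace: expected noise crossings at 3.5 SD are ~0.2, so the
        # only event is the inserted 10-SD template
        wf = gc.generate_waveform("RS", 0)
        tr = gc.generate_raw_trace([(wf, np.array([5.0]))], 10.0, noise_sd=1.0,
                                   fs=40000.0, rng=rng, amplitude=10.0)
        det = gc.detect_spikes(tr)
        assert len(det) == 1
        assert abs(det[0] - 5.0) < 1.0

    def test_unit_substreams_stable_when_units_added(self):
        u1 = [gc.UnitSpec(unit_id="u000", site_id="s0", coding_alpha=0.0)]
        u2 = u1 + [gc.UnitSpec(unit_id="u001", site_id="s0", coding_alpha=1.0)]
        a = gc.generate_session(gc.TaskConfig(seed=11), units=u1, n_trials_per_target=2)
        b = gc.generate_session(gc.TaskConfig(seed=11), units=u2, n_trials_per_target=2)
        sa = a.spikes[a.spikes.unit_id == "u000"].reset_index(drop=True)
        sb = b.spikes[b.spikes.unit_id == "u000"].reset_index(drop=True)
        assert sa.equals(sb)


def test_sampled_population_is_valid_and_deterministic():
    u1 = sample_units(20, seed=5)
    u2 = sample_units(20, seed=5)
    assert [u.unit_id for u in u1] == [u.unit_id for u in u2]
    assert all(u1[i].rf_sigma == u2[i].rf_sigma for i in range(20))
    assert {u.cell_class for u in u1} <= {"RS", "FS", "triphasic"}
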