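"""Spike detection, saccade events, waveform classification, epoch rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import gazecode as gc
from gazecode.signals import RawTrace, SignalConfig, SpikeTrain, Waveform
from conftest import make_trials


def _biphasic(width_samples, pre_amp=0.0, dt_us=25.0, n=60, trough=20):
    k = np.arange(n, dtype=float)
    s = -np.exp(-((k - trough) ** 2) / 18.0)
    s += 0.4 * np.exp(-((k - trough - width_samples) ** 2) / (2 * (width_samples / 2.5) ** 2))
    if pre_amp:
        s += pre_amp * 0.4 * np.exp(-((k - (trough - 9)) ** 2) / 12.5)
    return Waveform(samples=s, dt_us=dt_us)


class TestDetectSpikes:
    def test_zero_trace_has_no_events(self):
        with pytest.warns(UserWarning):
            out = gc.detect_spikes(RawTrace(samples=np.zeros(1000), fs=40000.0))
        assert len(out) == 0

    def test_single_large_peak_detected_at_its_sample(self, rng):
        x = rng.normal(0, 1, 40000)
        x[20000] += 10.0 * 1.0
        t = gc.detect_spikes(RawTrace(samples=x, fs=40000.0))
        assert np.any(np.abs(t - 500.0) < 0.2)

    def test_full_recall_on_inserted_templates(self, rng):
        wf = _biphasic(14)
        times = np.sort(rng.uniform(50, 950, 50))
        times = times[np.concatenate(([True], np.diff(times) > 5.0))]
        tr = gc.generate_raw_trace([(wf, times)], 1000.0, noise_sd=1.0, fs=40000.0, rng=rng, amplitude=8.0)
        det = gc.detect_spikes(tr)
        hits = sum(np.any(np.abs(det - t) < 1.5) for t in tr.ground_truth_times)
        assert hits == len(tr.ground_truth_times)

    def test_false_positive_rate_matches_gaussian_tail(self, rng):
        n = 1_000_000
        tr = RawTrace(samples=rng.normal(0, 1, n), fs=40000.0)
        events = gc.detect_spikes(tr)
        p = 2 * stats.norm.sf(3.5)
        expect = n * p
        assert abs(len(events) - expect) <= 3 * np.sqrt(expect) + 0.02 * expect


class TestDetectSaccade:
    def test_threshold_crossings_give_onset_offset(self):
        v = np.zeros(600)
        v[300:350] = 100.0  # above 50 at 300 ms, below 30 at 350 ms
        assert gc.detect_saccade(v, dt_ms=1.0) == (300.0, 350.0)

    def test_subthreshold_velocity_returns_none(self):
        assert gc.detect_saccade(np.full(500, 40.0)) is None

    def test_first_event_wins_then_rerun_finds_second(self):
        v = np.zeros(1000)
        v[200:250] = 90.0
        v[600:660] = 80.0
        on, off = gc.detect_saccade(v)
        assert (on, off) == (200.0, 250.0)
        on2, off2 = gc.detect_saccade(v[int(off):], t0_ms=off)
        assert (on2, off2) == (600.0, 660.0)

    def test_open_ended_event_flagged(self):
        v = np.concatenate([np.zeros(100), np.full(100, 90.0)])
        with pytest.warns(UserWarning):
            on, off = gc.detect_saccade(v)
        assert on == 100.0 and off is None


class TestClassifyWaveform:
    def test_width_over_250us_is_regular_spiking(self):
        assert gc.classify_waveform(_biphasic(12)) == "RS"  # 300 us

    def test_width_at_250us_is_fast_spiking(self):
        assert gc.classify_waveform(_biphasic(10)) == "FS"  # exactly 250 us

    def test_initial_positive_phase_is_triphasic(self):
        assert gc.classify_waveform(_biphasic(12, pre_amp=0.6)) == "triphasic"

    def test_monotone_waveform_rejected(self):
        with pytest.raises(ValueError):
            gc.classify_waveform(Waveform(samples=np.linspace(-1, 0, 20)))

    @pytest.mark.parametrize("cls", ["RS", "FS", "triphasic"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_generator_round_trip(self, cls, seed):
        assert gc.classify_waveform(gc.generate_waveform(cls, seed)) == cls


class TestReconstructMu:
    def test_counts_add(self):
        a = SpikeTrain("a", 0, [10.0, 20.0, 30.0])
        b = SpikeTrain("b", 0, [5.0, 15.0, 25.0, 35.0, 45.0])
        assert len(gc.reconstruct_mu([a, b]).spike_times) == 8

    def test_single_train_identity_and_empty(self):
        a = SpikeTrain("a", 0, [1.0, 2.0])
        assert np.array_equal(gc.reconstruct_mu([a]).spike_times, [1.0, 2.0])
        assert len(gc.reconstruct_mu([]).spike_times) == 0

    def test_mixed_sites_rejected(self):
        a = SpikeTrain("a", 0, [1.0])
        b = SpikeTrain("b", 0, [2.0])
        with pytest.raises(ValueError):
            gc.reconstruct_mu([a, b], site_of={"a": "s0", "b": "s1"})

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.lists(st.floats(0, 100), max_size=8), min_size=2, max_size=4), st.randoms())
    def test_order_independent_and_associative(self, groups, pyrandom):
        trains = [SpikeTrain(f"u{i}", 0, sorted(g)) for i, g in enumerate(groups)]
        direct = gc.reconstruct_mu(trains).spike_times
        shuffled = list(trains)
        pyrandom.shuffle(shuffled)
        assert np.array_equal(gc.reconstruct_mu(shuffled).spike_times, direct)
        staged = gc.reconstruct_mu([gc.reconstruct_mu(trains[:2]), *trains[2:]]).spike_times
        assert np.array_equal(staged, direct)


class TestEpochRate:
    def test_counts_over_window_length(self):
        assert gc.epoch_rate(np.array([10.0, 20, 30, 40, 50]), (0.0, 100.0)) == 50.0
        assert gc.epoch_rate(np.empty(0), (0.0, 100.0)) == 0.0

    def test_half_open_boundaries(self):
        assert gc.epoch_rate(np.array([0.0, 100.0]), (0.0, 100.0)) == 10.0  # start in, end out

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.lists(st.floats(0, 200), max_size=30), st.floats(10, 190))
    def test_additive_over_window_partition(self, times, split):
        times = np.sort(times)
        whole = gc.epoch_rate(times, (0.0, 200.0)) * 0.2
        parts = gc.epoch_rate(times, (0.0, split)) * split / 1000.0
        parts += gc.epoch_rate(times, (split, 200.0)) * (200.0 - split) / 1000.0
        assert parts == pytest.approx(whole)


class TestExcludeOutliers:
    def test_identical_endpoints_keep_everything(self):
        trials = make_trials([dict(gaze_x=1.0, gaze_y=1.0)] * 5)
        kept, log = gc.exclude_outlier_trials(trials)
        assert len(kept) == 5 and len(log) == 0

    def test_single_outlier_removed_with_mean_including_it(self):
        rows = [dict(targ_x=0.0, gaze_x=0.0, gaze_y=0.0)] * 9 + [dict(targ_x=0.0, gaze_x=5.0, gaze_y=0.0)]
        kept, log = gc.exclude_outlier_trials(make_trials(rows), SignalConfig(endpoint_excl=2.0))
        assert len(kept) == 9
        assert log["distance"].iloc[0] == pytest.approx(4.5)

    def test_infinite_threshold_keeps_everything(self, demo_session):
        kept, log = gc.exclude_outlier_trials(demo_session.trials, SignalConfig(endpoint_excl=1e9))
        assert len(kept) == len(demo_session.trials) and len(log) == 0
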