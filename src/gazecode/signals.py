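"""Signal-level processing: spike detection, saccade events, waveform
classification, multiunit reconstruction, epoch rates, trial exclusion.

Conventions: positions in degrees, times in ms relative to trial start,
rates in spikes/s.  Spike-count windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "Waveform",
    "RawTrace",
    "SignalConfig",
    "EpochConfig",
    "detect_spikes",
    "detect_saccade",
    "classify_waveform",
    "reconstruct_mu",
    "epoch_rate",
    "epoch_rate_matrix",
    "exclude_outlier_trials",
]


@dataclass
class SpikeTrain:
    """Sorted spike times (ms from trial start) of one unit in one trial."""

    unit_id: str
    trial_id: int
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike times must be nondecreasing")


@dataclass
class Waveform:
    """Action-potential template: voltage samples at ``dt_us`` µs spacing."""

    samples: np.ndarray
    dt_us: float = 25.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) < 8:
            raise ValueError("waveform needs at least 8 samples")
        if self.dt_us <= 0:
            raise ValueError("dt_us must be positive")


@dataclass
class RawTrace:
    """Continuous voltage trace from one site in one trial."""

    samples: np.ndarray
    fs: float
    site_id: str = ""
    trial_id: int = -1
    ground_truth_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")


@dataclass
class SignalConfig:
    """Detection/classification thresholds.

    detect_k: spike-detection threshold in robust SDs of the trace.
    dead_time: merge window for threshold crossings, ms.
    split_threshold_us: regular/fast-spiking split on trough-to-peak width.
    triphasic_ratio: minimum pre-trough positive phase, as a fraction of the
        post-trough peak, for a waveform to count as triphasic.
    sacc_on_v / sacc_off_v / head_off_v: velocity criteria, deg/s.
    endpoint_excl: gaze-endpoint exclusion radius about the per-target mean.
    """

    detect_k: float = 3.5
    dead_time: float = 1.0
    split_threshold_us: float = 250.0
    triphasic_ratio: float = 0.3
    sacc_on_v: float = 50.0
    sacc_off_v: float = 30.0
    head_off_v: float = 15.0
    endpoint_excl: float = 2.0

    def __post_init__(self) -> None:
        for name in ("detect_k", "dead_time", "split_threshold_us", "triphasic_ratio",
                     "sacc_on_v", "sacc_off_v", "head_off_v", "endpoint_excl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EpochConfig:
    """Analysis windows: visual 80–180 ms after target onset; motor −50..+50 ms
    around saccade onset."""

    visual_window: tuple[float, float] = (80.0, 180.0)
    motor_window: tuple[float, float] = (-50.0, 50.0)
    baseline_window: tuple[float, float] = (-100.0, 0.0)  # relative to target onset

    def __post_init__(self) -> None:
        for name in ("visual_window", "motor_window", "baseline_window"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} start must precede end")


def detect_spikes(trace: RawTrace, cfg: SignalConfig | None = None) -> np.ndarray:
    """Threshold-crossing spike detection on a raw voltage trace.

    The trace is centered on its median and the noise SD estimated robustly
    as 1.4826·MAD, so inserted spikes do not inflate the estimate.  Samples
    whose absolute deviation exceeds ``detect_k`` SDs (either polarity)
    form events; crossings separated by less than ``dead_time`` merge and
    each event is stamped at the sample of largest absolute deviation.

    Returns event times in ms.
    """
    cfg = cfg or SignalConfig()
    x = trace.samples
    if len(x) == 0:
        return np.empty(0)
    center = np.median(x)
    dev = np.abs(x - center)
    sd = 1.4826 * np.median(dev)
    if sd == 0:
        warnings.warn("trace has zero robust SD; no spikes detected")
        return np.empty(0)
    above = dev > cfg.detect_k * sd
    if not above.any():
        return np.empty(0)
    idx = np.flatnonzero(above)
    gap = int(np.ceil(cfg.dead_time * 1e-3 * trace.fs))
    breaks = np.flatnonzero(np.diff(idx) > gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    times = np.empty(len(starts))
    for k, (s, e) in enumerate(zip(starts, ends)):
        run = idx[s : e + 1]
        peak = run[np.argmax(dev[run])]
        times[k] = peak / trace.fs * 1000.0
    return times


def detect_saccade(
    velocity: np.ndarray,
    dt_ms: float = 1.0,
    cfg: SignalConfig | None = None,
    t0_ms: float = 0.0,
) -> tuple[float, float | None] | None:
    """Velocity-threshold saccade detection on a uniformly sampled trace.

    Onset is the first sample where velocity rises above ``sacc_on_v``;
    offset the first subsequent sample where it falls below ``sacc_off_v``.
    Returns ``(onset_ms, offset_ms)``; ``offset_ms`` is None (open-ended)
    when velocity never drops back below threshold, and the whole result is
    None when no onset exists.
    """
    cfg = cfg or SignalConfig()
    v = np.asarray(velocity, dtype=float)
    on = np.flatnonzero(v > cfg.sacc_on_v)
    if len(on) == 0:
        return None
    i_on = on[0]
    off = np.flatnonzero(v[i_on:] < cfg.sacc_off_v)
    if len(off) == 0:
        warnings.warn("saccade offset not reached; event is open-ended")
        return (t0_ms + i_on * dt_ms, None)
    return (t0_ms + i_on * dt_ms, t0_ms + (i_on + off[0]) * dt_ms)


def classify_waveform(w: Waveform, cfg: SignalConfig | None = None) -> str:
    """Classify a waveform as ``RS``, ``FS``, or ``triphasic``.

    Triphasic waveforms carry an initial positive phase of at least
    ``triphasic_ratio`` of the post-trough peak before the global trough.
    Otherwise the trough-to-peak width decides: > split threshold (250 µs)
    is regular spiking, ≤ is fast spiking.
    """
    cfg = cfg or SignalConfig()
    s = w.samples
    i_trough = int(np.argmin(s))
    post = s[i_trough + 1 :]
    if len(post) == 0 or post.max() <= s[i_trough]:
        raise ValueError("waveform has no identifiable trough-to-peak structure")
    i_peak = i_trough + 1 + int(np.argmax(post))
    peak_amp = s[i_peak]
    if peak_amp <= 0:
        raise ValueError("no positive post-trough peak; cannot classify")
    pre = s[:i_trough]
    if len(pre) and pre.max() >= cfg.triphasic_ratio * peak_amp:
        return "triphasic"
    width_us = (i_peak - i_trough) * w.dt_us
    return "RS" if width_us > cfg.split_threshold_us else "FS"


def reconstruct_mu(
    trains: Sequence[SpikeTrain], site_of: dict[str, str] | None = None
) -> SpikeTrain:
    """Reconstructed multiunit train: merged spikes of all same-site units.

    Every input unit contributes regardless of tuning or responsiveness;
    the output is the sorted multiset union.  When a unit-to-site mapping
    is supplied, mixing units from different sites is an error.
    """
    trains = list(trains)
    if not trains:
        return SpikeTrain(unit_id="MU", trial_id=-1, spike_times=np.empty(0))
    trial_ids = {t.trial_id for t in trains}
    if len(trial_ids) > 1:
        raise ValueError("cannot merge trains from different trials")
    if site_of is not None:
        sites = {site_of[t.unit_id] for t in trains}
        if len(sites) > 1:
            raise ValueError(f"cannot merge trains from different sites: {sorted(sites)}")
    merged = np.sort(np.concatenate([t.spike_times for t in trains]))
    return SpikeTrain(unit_id="MU", trial_id=trains[0].trial_id, spike_times=merged)


def epoch_rate(spike_times: np.ndarray | SpikeTrain, window: tuple[float, float], align: float = 0.0) -> float:
    """Firing rate in ``[align+start, align+end)``: count / window length (s)."""
    times = spike_times.spike_times if isinstance(spike_times, SpikeTrain) else np.asarray(spike_times, dtype=float)
    lo, hi = window
    if not lo < hi:
        raise ValueError("window start must precede end")
    n = int(np.sum((times >= align + lo) & (times < align + hi)))
    return n / ((hi - lo) / 1000.0)


def epoch_rate_matrix(
    trials: pd.DataFrame,
    spikes: pd.DataFrame,
    unit_id: str,
    window: tuple[float, float],
    align_col: str,
) -> np.ndarray:
    """Per-trial epoch rates for one unit, aligned to an event column.

    ``spikes`` has columns ``unit_id, trial_id, t_ms``; rates are returned
    in the row order of ``trials``.
    """
    sub = spikes[spikes["unit_id"] == unit_id]
    by_trial = {tid: g["t_ms"].to_numpy() for tid, g in sub.groupby("trial_id")}
    rates = np.empty(len(trials))
    for i, row in enumerate(trials.itertuples(index=False)):
        times = by_trial.get(row.trial_id, np.empty(0))
        rates[i] = epoch_rate(times, window, getattr(row, align_col))
    return rates


def exclude_outlier_trials(
    trials: pd.DataFrame, cfg: SignalConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove trials whose gaze endpoint strays from the per-target mean.

    A single pass: for each target, the mean endpoint over *all* its trials
    (outliers included) is computed, and trials farther than
    ``endpoint_excl`` degrees from that mean are dropped.  Returns the kept
    trials plus a removal log (trial_id, target, distance).
    """
    cfg = cfg or SignalConfig()
    g = trials.groupby(["targ_x", "targ_y"])[["gaze_x", "gaze_y"]].transform("mean")
    dist = np.hypot(trials["gaze_x"] - g["gaze_x"], trials["gaze_y"] - g["gaze_y"])
    drop = dist > cfg.endpoint_excl
    log = pd.DataFrame(
        {
            "trial_id": trials.loc[drop, "trial_id"].to_numpy(),
            "targ_x": trials.loc[drop, "targ_x"].to_numpy(),
            "targ_y": trials.loc[drop, "targ_y"].to_numpy(),
            "distance": dist[drop].to_numpy(),
        }
    )
    return trials.loc[~drop].reset_index(drop=True), log


def spike_trains_by_trial(spikes: pd.DataFrame, unit_id: str) -> dict[int, np.ndarray]:
    """Spike times per trial for one unit (helper for MU reconstruction)."""
    sub = spikes[spikes["unit_id"] == unit_id]
    return {tid: np.sort(g["t_ms"].to_numpy()) for tid, g in sub.groupby("trial_id")}
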