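"""Synthetic memory-guided gaze sessions with known ground truth.

The generator emulates a head-unrestrained, memory-delay gaze paradigm: a
fixation point jittered from trial to trial, a brief target flash on a
rectangular array, a visual mask, a variable second memory delay, and a
gaze shift whose endpoint carries both isotropic memory error and a
partial attraction toward a shifted landmark (the landmark jumps 8° in one
of eight radial directions on 90% of trials).  Gaze is decomposed into
head-in-space and eye-in-head components by a 2D additive convention, so
eye-, head-, and space-frame models of target and gaze are mutually
dissociable through the natural (simulated) variability.

Each simulated unit fires as an inhomogeneous Poisson process whose rate
is the sum of a baseline, a visual burst, a delay plateau, and a
perisaccadic burst; the spatial factor of each component is a closed
(Gaussian) or open (rectified-linear gradient) response field evaluated at
the unit's coded point on the target–gaze continuum.  The coded continuum
position α may be constant, differ per epoch, or ramp linearly across the
trial — the ground truth the fitting pipeline is asked to recover.

All randomness flows from one seed; behavior, each unit's spikes, each
waveform, and each raw trace draw from independent substreams keyed by
(seed, role, index) so that adding units never perturbs existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signals import RawTrace, SpikeTrain, Waveform

__all__ = [
    "TaskConfig",
    "UnitSpec",
    "Session",
    "ConfigError",
    "generate_session",
    "sample_units",
    "sample_gaze_endpoint",
    "simulate_unit",
    "generate_waveform",
    "generate_raw_trace",
]

# fixed task timing (ms): fixation hold, target flash, first delay, mask
T_TARGET_ON = 500.0
TARGET_DUR = 100.0
DELAY1 = 300.0
MASK_DUR = 200.0
REACTION_RANGE = (150.0, 300.0)

# substream role keys
_BEHAVIOR, _UNITS, _SPIKES, _WAVEFORMS, _TRACES = 1, 2, 3, 4, 5


class ConfigError(ValueError):
    """Invalid task configuration; the message names the offending field."""


@dataclass
class TaskConfig:
    """Parameters of the simulated paradigm (degrees, ms, probabilities).

    Defaults follow the task's standard regime: 4×4 target array at 8°
    spacing, fixation jitter within a 10° window, landmark 11° from the
    target, an 8° landmark shift in one of 8 radial directions on 90% of
    trials, second memory delay 200–600 ms, and a gaze endpoint that
    inherits a fraction ``shift_attraction`` of the landmark shift plus
    isotropic Gaussian error.
    """

    grid_nx: int = 4
    grid_ny: int = 4
    target_spacing: float = 8.0
    fixation_jitter_window: float = 10.0
    landmark_offset: float = 11.0
    landmark_shift: float = 8.0
    n_shift_directions: int = 8
    p_shift: float = 0.9
    reward_radius: float = 10.0
    delay2_range: tuple[float, float] = (200.0, 600.0)
    shift_attraction: float = 0.4
    endpoint_noise_sd: float = 4.5
    head_contribution: float = 0.3
    head_jitter_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (2 <= self.grid_nx <= 10 and 2 <= self.grid_ny <= 10):
            raise ConfigError("grid_nx/grid_ny must be integers in [2, 10]")
        for name in ("target_spacing", "fixation_jitter_window", "landmark_offset",
                     "landmark_shift", "reward_radius", "endpoint_noise_sd", "head_jitter_sd"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ConfigError(f"{name} must be finite and nonnegative")
        if self.n_shift_directions < 1:
            raise ConfigError("n_shift_directions must be at least 1")
        if not (0.0 <= self.p_shift <= 1.0):
            raise ConfigError("p_shift must lie in [0, 1]")
        if not (0.0 <= self.shift_attraction <= 1.0):
            raise ConfigError("shift_attraction must lie in [0, 1]")
        if not (0.0 <= self.head_contribution <= 1.0):
            raise ConfigError("head_contribution must lie in [0, 1]")
        lo, hi = self.delay2_range
        if not (0 <= lo <= hi):
            raise ConfigError("delay2_range must be an ordered nonnegative pair")


@dataclass
class UnitSpec:
    """Ground-truth description of one simulated unit.

    ``coding_alpha`` sets the point on the target–gaze continuum the unit
    encodes: a float (same in all epochs), a mapping with keys
    ``visual``/``delay``/``motor``, or ``("ramp", a0, a1)`` for a linear
    progression from a0 at the visual burst to a1 at saccade onset.
    Untuned units (``tuned=False``) keep the same temporal profile but a
    position-independent spatial factor.
    """

    unit_id: str
    site_id: str
    cell_class: str = "RS"
    coding_alpha: float | Mapping[str, float] | tuple = 0.0
    rf_center: tuple[float, float] = (0.0, 0.0)
    rf_sigma: float = 7.0
    rf_shape: str = "closed"
    baseline_rate: float = 8.0
    visual_gain: float = 150.0
    delay_gain: float = 25.0
    motor_gain: float = 150.0
    visual_latency: float = 70.0
    tuned: bool = True

    def __post_init__(self) -> None:
        if self.cell_class not in ("RS", "FS", "triphasic"):
            raise ConfigError("cell_class must be RS, FS, or triphasic")
        if self.rf_shape not in ("closed", "open"):
            raise ConfigError("rf_shape must be 'closed' or 'open'")
        if self.rf_sigma <= 0:
            raise ConfigError("rf_sigma must be positive")
        for name in ("baseline_rate", "visual_gain", "delay_gain", "motor_gain"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")


@dataclass
class Session:
    """One simulated recording session: behavior, units, spikes, waveforms."""

    config: TaskConfig
    trials: pd.DataFrame
    units: list[UnitSpec]
    spikes: pd.DataFrame
    waveforms: dict[str, Waveform] = field(default_factory=dict)
    raw_traces: list[RawTrace] | None = None

    def spike_trains(self, unit_id: str) -> dict[int, np.ndarray]:
        sub = self.spikes[self.spikes["unit_id"] == unit_id]
        out: dict[int, np.ndarray] = {
            int(t): np.sort(g["t_ms"].to_numpy()) for t, g in sub.groupby("trial_id")
        }
        for tid in self.trials["trial_id"]:
            out.setdefault(int(tid), np.empty(0))
        return out

    def validate(self) -> None:
        unit_ids = {u.unit_id for u in self.units}
        trial_ids = set(self.trials["trial_id"].astype(int))
        if len(self.trials) < 1:
            raise ValueError("session has no trials")
        if not set(self.spikes["unit_id"]).issubset(unit_ids):
            raise ValueError("spike references an unknown unit_id")
        if not set(self.spikes["trial_id"].astype(int)).issubset(trial_ids):
            raise ValueError("spike references an unknown trial_id")


def _rng(seed: int, role: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(role), int(index)])


def sample_gaze_endpoint(
    target: np.ndarray,
    landmark: np.ndarray,
    landmark_shifted: np.ndarray,
    omega: float,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaze endpoint ``G = T + ω·(L′ − L) + ε`` in space coordinates.

    ω is the fraction of the landmark shift inherited by gaze and ε is
    isotropic Gaussian error with SD σ per axis.
    """
    if sigma < 0:
        raise ConfigError("endpoint noise SD must be nonnegative")
    if not (0.0 <= omega <= 1.0):
        raise ConfigError("shift attraction must lie in [0, 1]")
    target = np.asarray(target, dtype=float)
    shift = np.asarray(landmark_shifted, dtype=float) - np.asarray(landmark, dtype=float)
    return target + omega * shift + rng.normal(0.0, sigma, size=2)


def _grid_targets(cfg: TaskConfig) -> np.ndarray:
    xs = (np.arange(cfg.grid_nx) - (cfg.grid_nx - 1) / 2.0) * cfg.target_spacing
    ys = (np.arange(cfg.grid_ny) - (cfg.grid_ny - 1) / 2.0) * cfg.target_spacing
    return np.array([(x, y) for y in ys for x in xs])


def _generate_trials(cfg: TaskConfig, n_trials_per_target: int) -> pd.DataFrame:
    rng = _rng(cfg.seed, _BEHAVIOR)
    targets = np.repeat(_grid_targets(cfg), n_trials_per_target, axis=0)
    order = rng.permutation(len(targets))
    targets = targets[order]
    rows = []
    half = cfg.fixation_jitter_window / 2.0
    oblique = np.deg2rad([45.0, 135.0, 225.0, 315.0])
    for tid, T in enumerate(targets):
        fix = rng.uniform(-half, half, size=2)
        head0 = cfg.head_contribution * fix + rng.normal(0.0, cfg.head_jitter_sd, size=2)
        eye0 = fix - head0
        ldir = oblique[rng.integers(4)]
        L = T + cfg.landmark_offset * np.array([np.cos(ldir), np.sin(ldir)])
        is_shift = rng.random() < cfg.p_shift
        if is_shift:
            k = int(rng.integers(cfg.n_shift_directions))
            th = 2.0 * np.pi * k / cfg.n_shift_directions
            Lp = L + cfg.landmark_shift * np.array([np.cos(th), np.sin(th)])
        else:
            k = -1
            Lp = L.copy()
        Tp = T + (Lp - L)
        G = sample_gaze_endpoint(T, L, Lp, cfg.shift_attraction, cfg.endpoint_noise_sd, rng)
        head1 = head0 + cfg.head_contribution * (G - fix) + rng.normal(0.0, cfg.head_jitter_sd, size=2)
        eye1 = G - head1
        delay2 = rng.uniform(*cfg.delay2_range)
        t_mask_on = T_TARGET_ON + TARGET_DUR + DELAY1
        t_mask_off = t_mask_on + MASK_DUR
        t_go = t_mask_off + delay2
        t_sacc_on = t_go + rng.uniform(*REACTION_RANGE)
        amplitude = float(np.hypot(*(G - fix)))
        t_sacc_off = t_sacc_on + 60.0 + amplitude
        rows.append(
            dict(
                trial_id=tid,
                fix_x=fix[0], fix_y=fix[1],
                head0_x=head0[0], head0_y=head0[1],
                eye0_x=eye0[0], eye0_y=eye0[1],
                head1_x=head1[0], head1_y=head1[1],
                eye1_x=eye1[0], eye1_y=eye1[1],
                targ_x=T[0], targ_y=T[1],
                land_x=L[0], land_y=L[1],
                land_shift_x=Lp[0], land_shift_y=Lp[1],
                vtarg_x=Tp[0], vtarg_y=Tp[1],
                gaze_x=G[0], gaze_y=G[1],
                t_target_on=T_TARGET_ON,
                t_mask_on=t_mask_on,
                t_mask_off=t_mask_off,
                t_go=t_go,
                t_sacc_on=t_sacc_on,
                t_sacc_off=t_sacc_off,
                t_end=t_sacc_off + 300.0,
                is_shift=bool(is_shift),
                shift_dir=k,
            )
        )
    return pd.DataFrame(rows)


def _spatial_factor(unit: UnitSpec, pos: np.ndarray) -> np.ndarray:
    """Closed (Gaussian) or open (rectified-linear gradient) field value."""
    pos = np.atleast_2d(pos)
    if not unit.tuned:
        return np.ones(len(pos))
    c = np.asarray(unit.rf_center, dtype=float)
    if unit.rf_shape == "closed":
        d2 = np.sum((pos - c) ** 2, axis=1)
        return np.exp(-d2 / (2.0 * unit.rf_sigma**2))
    norm = np.hypot(*c)
    u = c / norm if norm > 0 else np.array([1.0, 0.0])
    proj = (pos - c) @ u
    return np.maximum(0.0, proj) / unit.rf_sigma


def _alpha_profile(unit: UnitSpec, trial, t: np.ndarray) -> tuple[np.ndarray | None, dict[str, float]]:
    """Per-epoch α values, or a per-ms α vector for ramping units."""
    ca = unit.coding_alpha
    if isinstance(ca, tuple) and len(ca) == 3 and ca[0] == "ramp":
        a0, a1 = float(ca[1]), float(ca[2])
        t_start = trial.t_target_on + 80.0
        t_stop = trial.t_sacc_on
        frac = np.clip((t - t_start) / max(t_stop - t_start, 1.0), 0.0, 1.0)
        return a0 + frac * (a1 - a0), {}
    if isinstance(ca, Mapping):
        av = float(ca.get("visual", 0.0))
        am = float(ca.get("motor", av))
        ad = float(ca.get("delay", 0.5 * (av + am)))
        return None, {"visual": av, "delay": ad, "motor": am}
    a = float(ca)
    return None, {"visual": a, "delay": a, "motor": a}


def simulate_unit(unit: UnitSpec, trial, rng: np.random.Generator) -> SpikeTrain:
    """Inhomogeneous-Poisson spike train of one unit in one trial.

    The rate profile is baseline + a Gaussian-in-time visual burst after
    target onset (latency ``visual_latency``), a delay plateau between mask
    onset and the go cue, and a perisaccadic motor burst; each component is
    scaled by the response-field value at the unit's coded continuum point
    for that epoch.  ``trial`` is a trials-table row (itertuples record or
    Series with attribute access).
    """
    t_end = float(trial.t_end)
    n_ms = int(np.ceil(t_end))
    t = np.arange(n_ms, dtype=float) + 0.5
    te = np.array([trial.targ_x - trial.fix_x, trial.targ_y - trial.fix_y])
    ge = np.array([trial.gaze_x - trial.fix_x, trial.gaze_y - trial.fix_y])
    ramp_alpha, epoch_alpha = _alpha_profile(unit, trial, t)

    def factor(alpha) -> np.ndarray:
        a = np.asarray(alpha, dtype=float)
        pos = te[None, :] + a.reshape(-1, 1) * (ge - te)[None, :]
        return _spatial_factor(unit, pos)

    t_vis_peak = float(trial.t_target_on) + unit.visual_latency + 55.0
    vis_t = np.exp(-((t - t_vis_peak) ** 2) / (2.0 * 45.0**2))
    # sustained memory/planning activity from the end of the visual burst
    # until the movement begins
    delay_t = ((t >= trial.t_target_on + 200.0) & (t < trial.t_sacc_on)).astype(float)
    mot_t = np.exp(-((t - float(trial.t_sacc_on)) ** 2) / (2.0 * 30.0**2))

    if ramp_alpha is not None:
        f_t = factor(ramp_alpha)
        rate = unit.baseline_rate + f_t * (
            unit.visual_gain * vis_t + unit.delay_gain * delay_t + unit.motor_gain * mot_t
        )
    else:
        f_vis = factor(epoch_alpha["visual"])[0]
        f_del = factor(epoch_alpha["delay"])[0]
        f_mot = factor(epoch_alpha["motor"])[0]
        rate = (
            unit.baseline_rate
            + unit.visual_gain * f_vis * vis_t
            + unit.delay_gain * f_del * delay_t
            + unit.motor_gain * f_mot * mot_t
        )
    counts = rng.poisson(rate * 1e-3)
    idx = np.repeat(np.arange(n_ms), counts)
    if len(idx) == 0:
        return SpikeTrain(unit.unit_id, int(trial.trial_id), np.empty(0))
    times = np.sort(idx + rng.random(len(idx)))
    return SpikeTrain(unit.unit_id, int(trial.trial_id), times)


def generate_waveform(cell_class: str, seed: int | np.random.Generator = 0) -> Waveform:
    """Synthetic mean spike waveform of the requested biophysical class.

    Regular-spiking templates have trough-to-peak width > 250 µs, fast-
    spiking ≤ 250 µs, and triphasic templates carry an initial positive
    phase at 0.6 of the post-trough peak.  Sampled at 25 µs (40 kHz).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt_us = 25.0
    n = 60
    i_trough = 20
    if cell_class == "RS":
        width_us = rng.uniform(300.0, 500.0)
    elif cell_class == "FS":
        width_us = rng.uniform(140.0, 225.0)
    elif cell_class == "triphasic":
        width_us = rng.uniform(300.0, 450.0)
    else:
        raise ConfigError("cell_class must be RS, FS, or triphasic")
    w_samp = max(4, int(round(width_us / dt_us)))
    i_peak = i_trough + w_samp
    k = np.arange(n, dtype=float)
    scale = rng.uniform(0.8, 1.2)
    s = -1.0 * np.exp(-((k - i_trough) ** 2) / (2.0 * 3.0**2))
    s += 0.4 * np.exp(-((k - i_peak) ** 2) / (2.0 * (w_samp / 2.5) ** 2))
    if cell_class == "triphasic":
        s += 0.6 * 0.4 * np.exp(-((k - (i_trough - 9)) ** 2) / (2.0 * 2.5**2))
    return Waveform(samples=scale * s, dt_us=dt_us)


def generate_raw_trace(
    site_units: Sequence[tuple[Waveform, np.ndarray]],
    duration_ms: float,
    noise_sd: float,
    fs: float,
    rng: np.random.Generator | int = 0,
    amplitude: float = 8.0,
    site_id: str = "",
    trial_id: int = -1,
) -> RawTrace:
    """White-noise voltage trace with spike templates inserted.

    ``site_units`` pairs each unit's waveform template with its spike times
    (ms); templates are scaled to ``amplitude``·noise_sd (trough depth) and
    inserted trough-aligned at each spike time.  Ground-truth times are
    recorded for detector validation.
    """
    if fs <= 0:
        raise ConfigError("fs must be positive")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be nonnegative")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = int(np.ceil(duration_ms * fs / 1000.0))
    x = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    all_times = []
    for wf, times in site_units:
        tpl = wf.samples
        src_t = np.arange(len(tpl)) * wf.dt_us * 1e-6  # s
        dst_t = np.arange(int(np.ceil(src_t[-1] * fs)) + 1) / fs
        tpl_fs = np.interp(dst_t, src_t, tpl)
        trough = int(np.argmin(tpl_fs))
        depth = -tpl_fs.min()
        gain = amplitude * (noise_sd if noise_sd > 0 else 1.0) / depth if depth > 0 else 1.0
        for tm in np.asarray(times, dtype=float):
            c = int(round(tm * 1e-3 * fs))
            lo = c - trough
            hi = lo + len(tpl_fs)
            a, b = max(lo, 0), min(hi, n)
            if a >= b:
                continue
            x[a:b] += gain * tpl_fs[a - lo : b - lo]
            all_times.append(tm)
    gt = np.sort(np.asarray(all_times)) if all_times else np.empty(0)
    return RawTrace(samples=x, fs=fs, site_id=site_id, trial_id=trial_id, ground_truth_times=gt)


def sample_units(
    n_units: int,
    seed: int = 0,
    units_per_site: int = 3,
    p_untuned: float = 0.0,
) -> list[UnitSpec]:
    """Draw a default unit population.

    Visual continuum positions cluster near the target code (80% near
    α = 0, 20% near α = 1); motor positions cluster near the gaze code
    (70% near α = 1).  Cell classes: 55% RS, 35% FS, 10% triphasic.
    """
    rng = _rng(seed, _UNITS)
    units = []
    for i in range(n_units):
        cls = rng.choice(["RS", "FS", "triphasic"], p=[0.55, 0.35, 0.10])
        av = rng.normal(0.0, 0.1) if rng.random() < 0.8 else rng.normal(1.0, 0.1)
        am = rng.normal(1.0, 0.1) if rng.random() < 0.7 else rng.normal(0.0, 0.1)
        av, am = float(np.clip(av, -0.2, 1.2)), float(np.clip(am, -0.2, 1.2))
        units.append(
            UnitSpec(
                unit_id=f"u{i:03d}",
                site_id=f"s{i // units_per_site:03d}",
                cell_class=str(cls),
                coding_alpha={"visual": av, "delay": 0.5 * (av + am), "motor": am},
                rf_center=tuple(rng.uniform(-8.0, 8.0, size=2)),
                rf_sigma=float(rng.uniform(5.0, 9.0)),
                rf_shape="closed" if rng.random() < 0.6 else "open",
                baseline_rate=float(rng.uniform(4.0, 12.0)),
                visual_gain=float(rng.uniform(100.0, 200.0)),
                delay_gain=float(rng.uniform(10.0, 30.0)),
                motor_gain=float(rng.uniform(100.0, 200.0)),
                visual_latency=float(rng.uniform(60.0, 90.0)),
                tuned=bool(rng.random() >= p_untuned),
            )
        )
    return units


def generate_session(
    config: TaskConfig,
    n_units: int | None = None,
    n_trials_per_target: int = 10,
    units: Sequence[UnitSpec] | None = None,
    with_traces: bool = False,
    trace_fs: float = 20000.0,
    trace_noise_sd: float = 1.0,
) -> Session:
    """Generate a full synthetic session (behavior + spiking + waveforms).

    Deterministic for a fixed ``config.seed``.  Either ``n_units`` (units
    drawn by :func:`sample_units`) or an explicit ``units`` list must be
    given.  With ``with_traces=True``, per-site raw voltage traces are
    synthesized for every trial (memory permitting; intended for small
    sessions).
    """
    config.validate()
    if n_trials_per_target < 1:
        raise ConfigError("n_trials_per_target must be at least 1")
    if units is None:
        if n_units is None or n_units < 1:
            raise ConfigError("n_units must be at least 1 when units are not supplied")
        units = sample_units(n_units, seed=config.seed)
    units = list(units)
    trials = _generate_trials(config, n_trials_per_target)

    frames = []
    for i, unit in enumerate(units):
        rng_u = _rng(config.seed, _SPIKES, i)
        for row in trials.itertuples(index=False):
            train = simulate_unit(unit, row, rng_u)
            if len(train.spike_times):
                frames.append(
                    pd.DataFrame(
                        {
                            "unit_id": train.unit_id,
                            "trial_id": train.trial_id,
                            "t_ms": train.spike_times,
                        }
                    )
                )
    spikes = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame({"unit_id": pd.Series(dtype=str), "trial_id": pd.Series(dtype=int), "t_ms": pd.Series(dtype=float)})
    )
    waveforms = {
        u.unit_id: generate_waveform(u.cell_class, _rng(config.seed, _WAVEFORMS, i))
        for i, u in enumerate(units)
    }
    session = Session(config=config, trials=trials, units=units, spikes=spikes, waveforms=waveforms)
    if with_traces:
        session.raw_traces = synthesize_traces(session, fs=trace_fs, noise_sd=trace_noise_sd)
    session.validate()
    return session


def synthesize_traces(
    session: Session, fs: float = 20000.0, noise_sd: float = 1.0, amplitude: float = 8.0
) -> list[RawTrace]:
    """Per-site, per-trial raw traces built from the session's own spikes."""
    sites: dict[str, list[UnitSpec]] = {}
    for u in session.units:
        sites.setdefault(u.site_id, []).append(u)
    trains = {u.unit_id: session.spike_trains(u.unit_id) for u in session.units}
    traces = []
    for s_idx, (site_id, site_units) in enumerate(sorted(sites.items())):
        for row in session.trials.itertuples(index=False):
            tid = int(row.trial_id)
            pairs = [
                (session.waveforms[u.unit_id], trains[u.unit_id].get(tid, np.empty(0)))
                for u in site_units
            ]
            rng = _rng(session.config.seed, _TRACES, s_idx * 1_000_000 + tid)
            traces.append(
                generate_raw_trace(
                    pairs, float(row.t_end), noise_sd, fs, rng,
                    amplitude=amplitude, site_id=site_id, trial_id=tid,
                )
            )
    return traces
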