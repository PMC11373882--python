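"""Time-normalized tracking of the target–gaze code across the trial.

Delays vary across trials, so the interval from 80 ms after target onset
to saccade onset is rescaled per trial into ``n_bins`` equal, half-
overlapping windows: with span S and overlap fraction o the bin width is
``w = S / (1 + (n − 1)(1 − o))`` (w = 2S/(n+1) at 50% overlap) and the
step ``w·(1 − o)``, so the bins tile the span exactly.  Rates are sampled
per bin, the continuum localizer run per unit per bin, and the population
mean α tracked through time.  Bins where the population's spatial
coherence does not exceed the pre-target baseline (one-sided Mann–Whitney)
are masked: with no demonstrable tuning, a best-fit α is meaningless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import frames
from .rf import FitConfig, KernelBank, _best_alpha_index, _best_h
from .simulate import Session
from .signals import EpochConfig, epoch_rate
from .tuning import TuningConfig

__all__ = ["TimeBinsConfig", "TimeCourse", "time_bins", "tg_time_course"]


@dataclass
class TimeBinsConfig:
    """Time-normalization layout: 14 half-overlapping bins spanning from
    ``span_start`` ms after target onset to saccade onset; the final bin's
    sampling window may extend ``final_extension_ms`` past saccade onset to
    include part of the perisaccadic window."""

    n_bins: int = 14
    overlap: float = 0.5
    span_start: float = 80.0
    final_extension_ms: float = 50.0
    mask_p: float = 0.05

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be at least 1")
        if not (0.0 <= self.overlap < 1.0):
            raise ValueError("overlap must lie in [0, 1)")


@dataclass
class TimeCourse:
    """Per-bin population summary of the continuum code."""

    table: pd.DataFrame  # bin, t_frac, mean_alpha, sem_alpha, n_tuned, prop_tuned, mean_ci, masked
    per_unit_alpha: np.ndarray  # (n_units, n_bins), NaN where untuned
    per_unit_ci: np.ndarray
    unit_ids: list[str]


def time_bins(span_start_ms: float, span_end_ms: float, cfg: TimeBinsConfig | None = None) -> np.ndarray:
    """Equal, overlapping windows tiling ``[span_start, span_end]`` exactly.

    Returns an ``(n_bins, 2)`` array of absolute (start, end) times; bin k
    covers ``[start + k·step, start + k·step + w)`` and the last bin ends
    exactly at the span end.
    """
    cfg = cfg or TimeBinsConfig()
    S = span_end_ms - span_start_ms
    if S <= 0:
        raise ValueError("span must have positive duration")
    n = cfg.n_bins
    w = S / (1.0 + (n - 1) * (1.0 - cfg.overlap))
    step = w * (1.0 - cfg.overlap) if n > 1 else 0.0
    starts = span_start_ms + step * np.arange(n)
    out = np.column_stack([starts, starts + w])
    out[-1, 1] = span_end_ms  # exact, despite float accumulation
    return out


def _bin_rates(trials: pd.DataFrame, trains: dict[int, np.ndarray], cfg: TimeBinsConfig) -> np.ndarray:
    """(n_trials, n_bins) firing rates in each trial's normalized windows."""
    rates = np.empty((len(trials), cfg.n_bins))
    for i, row in enumerate(trials.itertuples(index=False)):
        wins = time_bins(row.t_target_on + cfg.span_start, row.t_sacc_on, cfg)
        wins[-1, 1] += cfg.final_extension_ms
        times = trains.get(int(row.trial_id), np.empty(0))
        for k, (lo, hi) in enumerate(wins):
            rates[i, k] = epoch_rate(times, (lo, hi))
    return rates


def _localize_and_test(
    bank: KernelBank,
    rates: np.ndarray,
    alpha_grid: np.ndarray,
    bandwidths: np.ndarray,
    tcfg: TuningConfig,
    rng: np.random.Generator,
) -> tuple[float, float, bool]:
    """Best α, coherence index, and tuned flag for one rate vector."""
    mp = bank.mean_press(rates)
    scale = float(np.mean(np.asarray(rates, dtype=float) ** 2))
    hsel = np.array([_best_h(row, bandwidths, scale) for row in mp])
    profile = mp[np.arange(len(alpha_grid)), hsel]
    ia = _best_alpha_index(profile, alpha_grid, scale)
    ih = int(hsel[ia])
    press_best = float(mp[ia, ih])
    perms = np.stack([rng.permutation(rates) for _ in range(tcfg.n_shuffles)])
    null = bank.shuffle_mean_press(perms, ia, ih)
    null_mean = float(null.mean())
    p_rank = (1.0 + int(np.sum(null <= press_best))) / (tcfg.n_shuffles + 1.0)
    tuned = p_rank <= (1.0 - tcfg.ci_level)
    ci = 1.0 - press_best / null_mean if null_mean > 0 else float("nan")
    return float(alpha_grid[ia]), ci, bool(tuned)


def tg_time_course(
    session: Session,
    fit_cfg: FitConfig | None = None,
    tuning_cfg: TuningConfig | None = None,
    bins_cfg: TimeBinsConfig | None = None,
    epoch_cfg: EpochConfig | None = None,
    seed: int = 0,
    unit_ids: list[str] | None = None,
    trials: pd.DataFrame | None = None,
) -> TimeCourse:
    """Track the population's continuum code across normalized time bins.

    For every unit and bin, the firing rate in that trial's bin window is
    fit along the T–G continuum and tested for spatial tuning against a
    rate-shuffle null; the population mean ± SEM of the tuned units' best
    α is reported per bin.  Bins whose across-unit coherence distribution
    does not significantly exceed the pre-target baseline coherence
    (Mann–Whitney, one-sided, p < ``mask_p``) are masked.
    """
    fit_cfg = fit_cfg or FitConfig()
    tuning_cfg = tuning_cfg or TuningConfig()
    bins_cfg = bins_cfg or TimeBinsConfig()
    epoch_cfg = epoch_cfg or EpochConfig()
    trials = session.trials if trials is None else trials
    uids = unit_ids if unit_ids is not None else [u.unit_id for u in session.units]
    if not uids:
        raise ValueError("no units to analyze")

    te, ge = frames.tg_anchors(trials)
    nb = bins_cfg.n_bins
    alphas = np.full((len(uids), nb), np.nan)
    cis = np.full((len(uids), nb), np.nan)
    tuned = np.zeros((len(uids), nb), dtype=bool)
    base_ci = np.full(len(uids), np.nan)

    for ui, uid in enumerate(uids):
        trains = session.spike_trains(uid)
        positions = [te + a * (ge - te) for a in fit_cfg.alpha_grid]
        bank = KernelBank(positions, fit_cfg.bandwidths, fit_cfg.knn_fallback)
        rates = _bin_rates(trials, trains, bins_cfg)
        base_rates = np.array(
            [
                epoch_rate(
                    trains.get(int(r.trial_id), np.empty(0)),
                    epoch_cfg.baseline_window,
                    r.t_target_on,
                )
                for r in trials.itertuples(index=False)
            ]
        )
        rng = np.random.default_rng([seed, 7, ui])
        _, bci, _ = _localize_and_test(bank, base_rates, fit_cfg.alpha_grid, fit_cfg.bandwidths, tuning_cfg, rng)
        base_ci[ui] = bci
        for k in range(nb):
            a, ci, tu = _localize_and_test(
                bank, rates[:, k], fit_cfg.alpha_grid, fit_cfg.bandwidths, tuning_cfg, rng
            )
            alphas[ui, k], cis[ui, k], tuned[ui, k] = a, ci, tu

    rows = []
    for k in range(nb):
        bin_cis = cis[:, k]
        ok = np.isfinite(bin_cis) & np.isfinite(base_ci)
        if ok.sum() >= 2 and np.ptp(np.concatenate([bin_cis[ok], base_ci[ok]])) > 0:
            _, p_mask = stats.mannwhitneyu(bin_cis[ok], base_ci[ok], alternative="greater")
        else:
            p_mask = 1.0
        masked = p_mask >= bins_cfg.mask_p
        sel = tuned[:, k]
        n_tuned = int(sel.sum())
        mean_a = float(np.mean(alphas[sel, k])) if (n_tuned and not masked) else float("nan")
        sem_a = (
            float(np.std(alphas[sel, k], ddof=1) / np.sqrt(n_tuned))
            if (n_tuned > 1 and not masked)
            else float("nan")
        )
        rows.append(
            dict(
                bin=k,
                t_frac=(k + 0.5) / nb,
                mean_alpha=mean_a,
                sem_alpha=sem_a,
                n_tuned=n_tuned,
                prop_tuned=n_tuned / len(uids),
                mean_ci=float(np.nanmean(bin_cis)) if np.isfinite(bin_cis).any() else float("nan"),
                mask_p=float(p_mask),
                masked=bool(masked),
            )
        )
    table = pd.DataFrame(rows)
    if table["masked"].all():
        warnings.warn("all time bins masked: population coherence never exceeded baseline")
    return TimeCourse(table=table, per_unit_alpha=alphas, per_unit_ci=cis, unit_ids=list(uids))
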