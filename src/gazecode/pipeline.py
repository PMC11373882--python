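"""End-to-end orchestration: simulate → process → fit → tune → track → summarize.

One :func:`run_pipeline` call generates a synthetic session, applies the
endpoint exclusion, fits every unit's visual and motor response fields
along the target–gaze continuum, tests spatial tuning, repeats the
analysis on two multiunit tracks — reconstructed MU (summed same-site
single-unit trains) and thresholded MU (spikes re-detected at 3.5 robust
SDs from synthetic raw traces) — runs the time-normalized population
analysis, and writes population statistics to a machine-readable report.
Identical configs and seeds yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import frames
from .popstats import (
    compare_groups,
    distribution_summary,
    mixture2_fit,
    paired_vm_shift,
    population_model_comparison,
    proportions_ztest,
    spearman_corr,
)
from .rf import FitConfig, compare_models, fit_tg_continuum
from .session_io import write_session
from .signals import EpochConfig, SignalConfig, detect_spikes, epoch_rate_matrix, exclude_outlier_trials
from .simulate import Session, TaskConfig, UnitSpec, generate_session, synthesize_traces
from .timecourse import TimeBinsConfig, tg_time_course
from .tuning import TuningConfig, spatial_tuning_test

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("gazecode")


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    task: TaskConfig = field(default_factory=TaskConfig)
    signal: SignalConfig = field(default_factory=lambda: SignalConfig(endpoint_excl=12.0))
    epochs: EpochConfig = field(default_factory=EpochConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    tuning: TuningConfig = field(default_factory=TuningConfig)
    bins: TimeBinsConfig = field(default_factory=TimeBinsConfig)
    n_units: int = 30
    n_trials_per_target: int = 10
    output_dir: str = "gazecode_run"
    seed: int = 0
    tracks: tuple[str, ...] = ("su", "mu_reconstructed", "mu_threshold")
    timecourse_tracks: tuple[str, ...] = ("su",)
    trace_fs: float = 20000.0
    trace_noise_sd: float = 1.0
    units: list[UnitSpec] | None = None  # explicit unit population override


def _continuum_fit_and_tune(te, ge, rates, fit_cfg, tuning_cfg, seed):
    cf = fit_tg_continuum(te, ge, rates, fit_cfg)
    pos = te + cf.alpha * (ge - te)
    tr = spatial_tuning_test(pos, rates, bandwidth=cf.bandwidth, cfg=tuning_cfg, seed=seed)
    return cf, tr


def _epoch_rates(trials, spikes, uid, epoch_cfg, epoch):
    if epoch == "visual":
        return epoch_rate_matrix(trials, spikes, uid, epoch_cfg.visual_window, "t_target_on")
    return epoch_rate_matrix(trials, spikes, uid, epoch_cfg.motor_window, "t_sacc_on")


def _mu_reconstructed_spikes(session: Session) -> tuple[pd.DataFrame, dict[str, str]]:
    """Summed same-site single-unit spikes, one pseudo-unit per site."""
    spikes = session.spikes.copy()
    site_of = {u.unit_id: u.site_id for u in session.units}
    spikes["unit_id"] = spikes["unit_id"].map(lambda u: f"MUr_{site_of[u]}")
    ids = {f"MUr_{s}": s for s in sorted({u.site_id for u in session.units})}
    return spikes.sort_values(["unit_id", "trial_id", "t_ms"], kind="stable").reset_index(drop=True), ids


def _mu_threshold_spikes(session: Session, cfg: RunConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    """Spikes re-detected from synthetic raw traces at the detection threshold."""
    traces = session.raw_traces or synthesize_traces(
        session, fs=cfg.trace_fs, noise_sd=cfg.trace_noise_sd
    )
    rows = []
    sites = set()
    for tr in traces:
        sites.add(tr.site_id)
        times = detect_spikes(tr, cfg.signal)
        for t in times:
            rows.append((f"MUt_{tr.site_id}", tr.trial_id, t))
    spikes = pd.DataFrame(rows, columns=["unit_id", "trial_id", "t_ms"])
    return spikes, {f"MUt_{s}": s for s in sorted(sites)}


_TRACK_IDS = {"su": 0, "mu_reconstructed": 1, "mu_threshold": 2}


def _analyze_track(
    track: str,
    trials: pd.DataFrame,
    spikes: pd.DataFrame,
    unit_ids: list[str],
    cfg: RunConfig,
) -> pd.DataFrame:
    """Cardinal-model comparison + continuum fit + tuning per unit per epoch."""
    pos_all = frames.model_positions(trials)
    te, ge = frames.tg_anchors(trials)
    rows = []
    for ui, uid in enumerate(unit_ids):
        for epoch in ("visual", "motor"):
            rates = _epoch_rates(trials, spikes, uid, cfg.epochs, epoch)
            if np.ptp(rates) == 0:
                log.warning("track=%s unit=%s epoch=%s: constant rates, skipped", track, uid, epoch)
                continue
            mc = compare_models(pos_all, rates, cfg.fit)
            cf, tr = _continuum_fit_and_tune(
                te, ge, rates, cfg.fit, cfg.tuning,
                seed=[cfg.seed, 11, _TRACK_IDS.get(track, 9), ui],
            )
            rows.append(
                dict(
                    track=track,
                    unit_id=uid,
                    epoch=epoch,
                    best_model=mc.best_label,
                    best_model_press=mc.mean_press[mc.best_label],
                    alpha=cf.alpha,
                    bandwidth=cf.bandwidth,
                    mean_press=cf.mean_press,
                    tuned=tr.tuned,
                    ci=tr.ci,
                    p_rank=tr.p_rank,
                    indeterminate=cf.indeterminate,
                    **{f"press_{m}": mc.mean_press[m] for m in pos_all},
                )
            )
    return pd.DataFrame(rows)


def _track_stats(fits: pd.DataFrame, track: str, seed: int) -> dict:
    """Distribution summaries, paired shift, and mixture fits for one track."""
    out: dict = {}
    sub = fits[fits["track"] == track]
    for epoch in ("visual", "motor"):
        tuned = sub[(sub["epoch"] == epoch) & sub["tuned"]]
        key = f"dist_{epoch}_{track}"
        if len(tuned) == 0:
            out[key] = {"n": 0, "empty": True}
            continue
        ds = distribution_summary(tuned["alpha"].to_numpy())
        out[key] = dataclasses.asdict(ds)
        if len(tuned) >= 4 and np.ptp(tuned["alpha"].to_numpy()) > 0:
            mx = mixture2_fit(tuned["alpha"].to_numpy(), seed=seed)
            out[f"mixture_{epoch}_{track}"] = dataclasses.asdict(mx)
    vis = sub[(sub["epoch"] == "visual") & sub["tuned"]].set_index("unit_id")["alpha"]
    mot = sub[(sub["epoch"] == "motor") & sub["tuned"]].set_index("unit_id")["alpha"]
    both = vis.index.intersection(mot.index)
    if len(both) >= 3:
        ps = paired_vm_shift(vis[both].to_numpy(), mot[both].to_numpy())
        out[f"paired_vm_{track}"] = dataclasses.asdict(ps)
    # across-unit cardinal-model comparison
    for epoch in ("visual", "motor"):
        tuned = sub[(sub["epoch"] == epoch) & sub["tuned"]]
        press_cols = [c for c in tuned.columns if c.startswith("press_")]
        if len(tuned) >= 2 and press_cols:
            by_model = {c[len("press_"):]: tuned[c].to_numpy() for c in press_cols}
            best, pvals = population_model_comparison(by_model)
            out[f"model_comparison_{epoch}_{track}"] = {"best": best, "p_values": pvals}
    return out


def _cross_track_stats(fits: pd.DataFrame, site_of: dict[str, str]) -> dict:
    """SU-vs-MU comparisons: distributions, proportions, site matching."""
    out: dict = {}
    su = fits[fits["track"] == "su"]
    mu = fits[fits["track"] == "mu_reconstructed"]
    for epoch in ("visual", "motor"):
        a = su[(su["epoch"] == epoch) & su["tuned"]]["alpha"].to_numpy()
        b = mu[(mu["epoch"] == epoch) & mu["tuned"]]["alpha"].to_numpy()
        if len(a) >= 2 and len(b) >= 2:
            mw_p, F, var_p = compare_groups(a, b)
            k1, k2 = int(np.sum(a < 0.5)), int(np.sum(b < 0.5))
            z, zp = proportions_ztest(k1, len(a), k2, len(b))
            out[f"su_vs_mu_{epoch}"] = {
                "mw_p": mw_p, "var_F": F, "var_p": var_p,
                "prop_z": z, "prop_p": zp,
                "frac_below_half_su": k1 / len(a), "frac_below_half_mu": k2 / len(b),
            }
        # site-matched rank correlation
        su_e = su[(su["epoch"] == epoch) & su["tuned"]].copy()
        mu_e = mu[(mu["epoch"] == epoch) & mu["tuned"]].copy()
        if len(su_e) and len(mu_e):
            su_e["site"] = su_e["unit_id"].map(site_of)
            mu_e["site"] = mu_e["unit_id"].str.replace("MUr_", "", regex=False)
            merged = su_e.groupby("site")["alpha"].mean().to_frame("su").join(
                mu_e.set_index("site")["alpha"].rename("mu"), how="inner"
            )
            if len(merged) >= 3 and merged["su"].nunique() > 1 and merged["mu"].nunique() > 1:
                rho, p = spearman_corr(merged["su"], merged["mu"])
                out[f"site_match_{epoch}"] = {"spearman_rho": rho, "p": p, "n_sites": len(merged)}
    return out


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write all intermediate files plus report.json."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        task = dataclasses.replace(cfg.task, seed=cfg.seed)
        log.info("stage=simulate seed=%d", cfg.seed)
        session = generate_session(
            task,
            n_units=cfg.n_units,
            n_trials_per_target=cfg.n_trials_per_target,
            units=cfg.units,
        )
        write_session(session, out / "session")

        log.info("stage=exclude threshold=%.2f deg", cfg.signal.endpoint_excl)
        kept, removed = exclude_outlier_trials(session.trials, cfg.signal)
        removed.to_csv(out / "excluded_trials.csv", index=False)
        for r in removed.itertuples(index=False):
            log.info("excluded trial_id=%d distance=%.3f", int(r.trial_id), r.distance)

        site_of = {u.unit_id: u.site_id for u in session.units}
        track_inputs: dict[str, tuple[pd.DataFrame, list[str]]] = {}
        if "su" in cfg.tracks:
            track_inputs["su"] = (session.spikes, [u.unit_id for u in session.units])
        if "mu_reconstructed" in cfg.tracks:
            sp, ids = _mu_reconstructed_spikes(session)
            track_inputs["mu_reconstructed"] = (sp, sorted(ids))
        if "mu_threshold" in cfg.tracks:
            log.info("stage=detect fs=%.0f k=%.1f", cfg.trace_fs, cfg.signal.detect_k)
            sp, ids = _mu_threshold_spikes(session, cfg)
            track_inputs["mu_threshold"] = (sp, sorted(ids))

        all_fits = []
        for track, (spikes, uids) in track_inputs.items():
            log.info("stage=fit track=%s n_units=%d n_trials=%d", track, len(uids), len(kept))
            all_fits.append(_analyze_track(track, kept, spikes, uids, cfg))
        fits = pd.concat([f for f in all_fits if len(f)], ignore_index=True) if all_fits else pd.DataFrame()
        fits.to_csv(out / "fits.csv", index=False)

        report: dict = {
            "seed": cfg.seed,
            "n_trials_total": int(len(session.trials)),
            "n_trials_kept": int(len(kept)),
            "n_units": len(session.units),
            "tracks": list(track_inputs),
        }
        if len(fits) == 0 or not fits["tuned"].any():
            warnings.warn("no tuned units in any track; population statistics skipped")
            report["empty_populations"] = True
        else:
            report["empty_populations"] = False
            for track in track_inputs:
                report.update(_track_stats(fits, track, seed=cfg.seed))
            if {"su", "mu_reconstructed"} <= set(track_inputs):
                report.update(_cross_track_stats(fits, site_of))

        for track in cfg.timecourse_tracks:
            if track not in track_inputs:
                continue
            spikes, uids = track_inputs[track]
            tc_session = Session(
                config=session.config,
                trials=kept,
                units=[UnitSpec(unit_id=u, site_id=u) for u in uids] if track != "su" else session.units,
                spikes=spikes,
                waveforms={},
            )
            log.info("stage=timecourse track=%s", track)
            tc = tg_time_course(
                tc_session, cfg.fit, cfg.tuning, cfg.bins, cfg.epochs, seed=cfg.seed,
                unit_ids=uids, trials=kept,
            )
            tc.table.to_csv(out / f"timecourse_{track}.csv", index=False)
            report[f"timecourse_{track}"] = {
                "mean_alpha": tc.table["mean_alpha"].tolist(),
                "prop_tuned": tc.table["prop_tuned"].tolist(),
                "masked": tc.table["masked"].tolist(),
            }

        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
            fh.write("\n")
        log.info("stage=report done")
        return report
    except Exception:
        log.exception("pipeline stage failed; partial outputs retained in %s", out)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
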