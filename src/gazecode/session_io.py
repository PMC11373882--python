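"""Plain-text session persistence.

A session directory holds ``trials.csv`` (one row per trial, space-frame
degrees), ``spikes.csv`` (unit_id, trial_id, t_ms), ``units.csv``,
``waveforms.csv`` (unit_id, sample_index, value, dt_us), ``config.yaml``,
and optionally ``traces.h5`` with raw voltage traces.  Readers validate
referential integrity and fail loudly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .signals import RawTrace, Waveform
from .simulate import Session, TaskConfig, UnitSpec

__all__ = ["write_session", "read_session"]

TRIAL_COLUMNS = [
    "trial_id",
    "fix_x", "fix_y",
    "head0_x", "head0_y", "eye0_x", "eye0_y",
    "head1_x", "head1_y", "eye1_x", "eye1_y",
    "targ_x", "targ_y",
    "land_x", "land_y", "land_shift_x", "land_shift_y",
    "vtarg_x", "vtarg_y",
    "gaze_x", "gaze_y",
    "t_target_on", "t_mask_on", "t_mask_off", "t_go", "t_sacc_on", "t_sacc_off", "t_end",
    "is_shift", "shift_dir",
]


def _alpha_to_str(ca) -> str:
    if isinstance(ca, tuple):
        return json.dumps(list(ca))
    if isinstance(ca, dict):
        return json.dumps(ca, sort_keys=True)
    return json.dumps(float(ca))


def _alpha_from_str(s: str):
    v = json.loads(s)
    if isinstance(v, list):
        return (v[0], *[float(x) for x in v[1:]])
    if isinstance(v, dict):
        return {k: float(x) for k, x in v.items()}
    return float(v)


def write_session(session: Session, outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    session.trials[TRIAL_COLUMNS].to_csv(out / "trials.csv", index=False)
    session.spikes.to_csv(out / "spikes.csv", index=False)
    units = pd.DataFrame(
        [
            dict(
                unit_id=u.unit_id,
                site_id=u.site_id,
                cell_class=u.cell_class,
                coding_alpha=_alpha_to_str(u.coding_alpha),
                rf_center_x=u.rf_center[0],
                rf_center_y=u.rf_center[1],
                rf_sigma=u.rf_sigma,
                rf_shape=u.rf_shape,
                baseline_rate=u.baseline_rate,
                visual_gain=u.visual_gain,
                delay_gain=u.delay_gain,
                motor_gain=u.motor_gain,
                visual_latency=u.visual_latency,
                tuned=u.tuned,
            )
            for u in session.units
        ]
    )
    units.to_csv(out / "units.csv", index=False)
    wf_rows = []
    for uid, wf in session.waveforms.items():
        for i, v in enumerate(wf.samples):
            wf_rows.append(dict(unit_id=uid, sample_index=i, value=v, dt_us=wf.dt_us))
    pd.DataFrame(wf_rows).to_csv(out / "waveforms.csv", index=False)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(session.config), fh, sort_keys=True)
    if session.raw_traces:
        import h5py

        with h5py.File(out / "traces.h5", "w") as h5:
            for k, tr in enumerate(session.raw_traces):
                g = h5.create_group(f"trace_{k:05d}")
                g.create_dataset("samples", data=tr.samples)
                g.attrs["fs"] = tr.fs
                g.attrs["site_id"] = tr.site_id
                g.attrs["trial_id"] = tr.trial_id
                if tr.ground_truth_times is not None:
                    g.create_dataset("ground_truth_times", data=tr.ground_truth_times)
    return out


def read_session(indir: str | Path) -> Session:
    ind = Path(indir)
    with open(ind / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    raw["delay2_range"] = tuple(raw["delay2_range"])
    config = TaskConfig(**raw)
    trials = pd.read_csv(ind / "trials.csv")
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trials.csv missing columns: {sorted(missing)}")
    spikes = pd.read_csv(ind / "spikes.csv")
    units_df = pd.read_csv(ind / "units.csv")
    units = [
        UnitSpec(
            unit_id=r.unit_id,
            site_id=r.site_id,
            cell_class=r.cell_class,
            coding_alpha=_alpha_from_str(r.coding_alpha),
            rf_center=(r.rf_center_x, r.rf_center_y),
            rf_sigma=r.rf_sigma,
            rf_shape=r.rf_shape,
            baseline_rate=r.baseline_rate,
            delay_gain=r.delay_gain,
            visual_gain=r.visual_gain,
            motor_gain=r.motor_gain,
            visual_latency=r.visual_latency,
            tuned=bool(r.tuned),
        )
        for r in units_df.itertuples(index=False)
    ]
    waveforms = {}
    wf_df = pd.read_csv(ind / "waveforms.csv")
    for uid, g in wf_df.groupby("unit_id"):
        g = g.sort_values("sample_index")
        waveforms[str(uid)] = Waveform(samples=g["value"].to_numpy(), dt_us=float(g["dt_us"].iloc[0]))
    traces = None
    if (ind / "traces.h5").exists():
        import h5py

        traces = []
        with h5py.File(ind / "traces.h5", "r") as h5:
            for k in sorted(h5):
                g = h5[k]
                traces.append(
                    RawTrace(
                        samples=g["samples"][()],
                        fs=float(g.attrs["fs"]),
                        site_id=str(g.attrs["site_id"]),
                        trial_id=int(g.attrs["trial_id"]),
                        ground_truth_times=g["ground_truth_times"][()] if "ground_truth_times" in g else None,
                    )
                )
    session = Session(config=config, trials=trials, units=units, spikes=spikes,
                      waveforms=waveforms, raw_traces=traces)
    session.validate()
    return session
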