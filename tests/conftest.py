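import numpy as np
import pandas as pd
import pytest

import gazecode as gc
from gazecode.signals import EpochConfig, epoch_rate_matrix

_TRIAL_DEFAULTS = dict(
    trial_id=0,
    fix_x=0.0, fix_y=0.0,
    head0_x=0.0, head0_y=0.0,
    eye0_x=0.0, eye0_y=0.0,
    head1_x=0.0, head1_y=0.0,
    eye1_x=0.0, eye1_y=0.0,
    targ_x=0.0, targ_y=0.0,
    land_x=11.0, land_y=0.0, land_shift_x=11.0, land_shift_y=0.0,
    vtarg_x=0.0, vtarg_y=0.0,
    gaze_x=0.0, gaze_y=0.0,
    t_target_on=500.0, t_mask_on=900.0, t_mask_off=1100.0, t_go=1400.0,
    t_sacc_on=1600.0, t_sacc_off=1700.0, t_end=2000.0,
    is_shift=False, shift_dir=-1,
)


def make_trials(rows):
    """Build a trials table from partial per-trial dicts, filling defaults.

    Keeps the additive frame convention consistent: eye0 = fix - head0 and
    eye1 = gaze - head1 unless explicitly overridden.
    """
    out = []
    for i, row in enumerate(rows):
        r = dict(_TRIAL_DEFAULTS)
        r["trial_id"] = i
        r.update(row)
        if "eye0_x" not in row:
            r["eye0_x"] = r["fix_x"] - r["head0_x"]
            r["eye0_y"] = r["fix_y"] - r["head0_y"]
        if "eye1_x" not in row:
            r["eye1_x"] = r["gaze_x"] - r["head1_x"]
            r["eye1_y"] = r["gaze_y"] - r["head1_y"]
        out.append(r)
    return pd.DataFrame(out)


def visual_rates(session, unit_id):
    cfg = EpochConfig()
    return epoch_rate_matrix(session.trials, session.spikes, unit_id, cfg.visual_window, "t_target_on")


def motor_rates(session, unit_id):
    cfg = EpochConfig()
    return epoch_rate_matrix(session.trials, session.spikes, unit_id, cfg.motor_window, "t_sacc_on")


@pytest.fixture(scope="session")
def demo_session():
    """Small default-regime session shared by read-only tests."""
    return gc.generate_session(gc.TaskConfig(seed=0), n_units=2, n_trials_per_target=5)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
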