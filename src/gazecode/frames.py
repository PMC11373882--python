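"""Egocentric spatial models for gaze-trial geometry.

Every candidate reference-frame model maps a trial's behavioral geometry to
a single 2D position (in degrees).  Frame composition is 2D additive:
``gaze_space = head_space + eye_in_head`` and a position expressed "in"
frame F is ``x_space − F_origin_space``.  Ten egocentric models are
considered:

====== =====================================================
Ts     target in space
Th     target in head (relative to initial head orientation)
Te     target in eye  (relative to initial gaze direction)
Gs     final gaze in space
Gh     final gaze in head
Ge     final gaze in eye
Eh     final eye-in-head orientation
Hs     final head-in-space orientation
dE     eye-in-head displacement (final − initial)
dH     head-in-space displacement (final − initial)
====== =====================================================

"In eye" coordinates are relative to the *initial* (pre-saccade) gaze
direction, which serves as the response-field origin.  Gaze displacement
is excluded from the candidate set because it is numerically
indistinguishable from Ge in this paradigm.

The target–gaze (T–G) continuum interpolates between the eye-centered
target and future-gaze models: ``x(α) = Te + α·(Ge − Te)``, so α = 0 is a
pure target code and α = 1 a pure gaze code; values outside [0, 1]
extrapolate beyond the two anchors.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

#: Canonical model order used throughout the package.
MODEL_NAMES = ("Ts", "Th", "Te", "Gs", "Gh", "Ge", "Eh", "Hs", "dE", "dH")

# trials-table column pairs used to build the models
_XY = {
    "fix": ("fix_x", "fix_y"),
    "head0": ("head0_x", "head0_y"),
    "eye0": ("eye0_x", "eye0_y"),
    "head1": ("head1_x", "head1_y"),
    "eye1": ("eye1_x", "eye1_y"),
    "targ": ("targ_x", "targ_y"),
    "gaze": ("gaze_x", "gaze_y"),
}


def _col(trials: pd.DataFrame, key: str) -> np.ndarray:
    cx, cy = _XY[key]
    return trials[[cx, cy]].to_numpy(dtype=float)


def model_positions(trials: pd.DataFrame) -> Mapping[str, np.ndarray]:
    """Per-trial 2D coordinates of all ten egocentric models.

    Parameters
    ----------
    trials
        Trials table with the behavioral geometry columns (``fix_x/y``,
        ``head0_x/y``, ``eye0_x/y``, ``head1_x/y``, ``eye1_x/y``,
        ``targ_x/y``, ``gaze_x/y``), all in space-frame degrees.

    Returns
    -------
    dict mapping model name to an ``(n_trials, 2)`` array of degrees.
    """
    T = _col(trials, "targ")
    G = _col(trials, "gaze")
    fix = _col(trials, "fix")
    head0 = _col(trials, "head0")
    head1 = _col(trials, "head1")
    eye0 = _col(trials, "eye0")
    eye1 = _col(trials, "eye1")
    pos = {
        "Ts": T,
        "Th": T - head0,
        "Te": T - fix,
        "Gs": G,
        "Gh": G - head0,
        "Ge": G - fix,
        "Eh": eye1,
        "Hs": head1,
        "dE": eye1 - eye0,
        "dH": head1 - head0,
    }
    for name, arr in pos.items():
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite geometry for model {name}")
    return pos


def model_positions_frame(trials: pd.DataFrame) -> pd.DataFrame:
    """Wide table of model positions, one ``<model>_x/_y`` column pair each."""
    pos = model_positions(trials)
    out = {"trial_id": trials["trial_id"].to_numpy()}
    for name in MODEL_NAMES:
        out[f"{name}_x"] = pos[name][:, 0]
        out[f"{name}_y"] = pos[name][:, 1]
    return pd.DataFrame(out)


def tg_position(trials: pd.DataFrame, alpha: float) -> np.ndarray:
    """Interpolated T–G continuum position ``Te + α·(Ge − Te)`` per trial."""
    if not np.isfinite(alpha):
        raise ValueError("alpha must be finite")
    te = _col(trials, "targ") - _col(trials, "fix")
    ge = _col(trials, "gaze") - _col(trials, "fix")
    return te + alpha * (ge - te)


def tg_anchors(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """The continuum anchors (Te, Ge) as ``(n, 2)`` arrays."""
    fix = _col(trials, "fix")
    return _col(trials, "targ") - fix, _col(trials, "gaze") - fix
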