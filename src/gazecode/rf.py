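"""Nonparametric response-field fitting with PRESS cross-validation.

A unit's response field — firing rate as a function of 2D position in some
candidate reference frame — is estimated by Gaussian-kernel (Nadaraya–
Watson) regression:

    f(q) = Σᵢ wᵢ rᵢ / Σᵢ wᵢ,   wᵢ = exp(−‖xᵢ − q‖² / (2h²))

with spatial bandwidth ``h`` in degrees.  Goodness of a candidate spatial
model is measured by the predicted residual error sum of squares (PRESS):
each trial's rate is predicted from a fit to all *other* trials (exact
leave-one-out, no approximation) and the mean squared residual taken.
The model/bandwidth with the lowest mean PRESS is "best".  Competing
models are compared with a Brown–Forsythe test on the per-trial residuals
at the best model's bandwidth.

The target–gaze continuum localizer repeats the bandwidth search at each
interpolation step α between the eye-centered target (α = 0) and future-
gaze (α = 1) models, returning the α with minimal PRESS — the unit's
position along the visuomotor transformation.

Estimators follow scikit-learn conventions (``fit``, ``predict``,
``get_params``; fitted attributes carry a trailing underscore) and compose
with sklearn model-selection tooling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "FitConfig",
    "FitResult",
    "ModelComparison",
    "ContinuumFit",
    "KernelResponseField",
    "TGContinuumLocalizer",
    "kernel_fit_predict",
    "press_residuals",
    "fit_model",
    "brown_forsythe",
    "compare_models",
    "fit_tg_continuum",
]

# kernel-sum underflow guard: fall back to k-NN only when the weight sum
# has truly vanished (denormal range), not merely become small
_EPS = 1e-290


def default_bandwidths() -> np.ndarray:
    """Bandwidth grid: 2–25° in 1° steps."""
    return np.arange(2.0, 26.0, 1.0)


def default_alpha_grid() -> np.ndarray:
    """Continuum grid: −0.2 to 1.2 in 0.1 steps (two steps beyond each anchor)."""
    return np.round(np.arange(-0.2, 1.2001, 0.1), 10)


@dataclass
class FitConfig:
    """Grids for bandwidth selection and continuum localization.

    Parameters
    ----------
    bandwidths
        Ascending kernel bandwidths in degrees.
    alpha_grid
        Continuum steps; must contain 0 and 1.
    knn_fallback
        Neighbors used for the unweighted-mean fallback when all kernel
        weights underflow at a query point.
    """

    bandwidths: np.ndarray = field(default_factory=default_bandwidths)
    alpha_grid: np.ndarray = field(default_factory=default_alpha_grid)
    knn_fallback: int = 3

    def __post_init__(self) -> None:
        self.bandwidths = np.asarray(self.bandwidths, dtype=float)
        self.alpha_grid = np.asarray(self.alpha_grid, dtype=float)
        if self.bandwidths.ndim != 1 or len(self.bandwidths) == 0:
            raise ValueError("bandwidths must be a nonempty 1D grid")
        if np.any(self.bandwidths <= 0) or np.any(np.diff(self.bandwidths) <= 0):
            raise ValueError("bandwidths must be positive and ascending")
        if not (np.isclose(self.alpha_grid, 0.0).any() and np.isclose(self.alpha_grid, 1.0).any()):
            raise ValueError("alpha_grid must contain 0 and 1")


@dataclass
class FitResult:
    """Best-bandwidth fit of one spatial model."""

    model_label: str
    bandwidth: float
    press_residuals: np.ndarray
    mean_press: float


@dataclass
class ModelComparison:
    """Outcome of testing all candidate spatial models against each other."""

    best_label: str
    bandwidth: float  # bandwidth of the best model's fit
    mean_press: dict[str, float]  # per model, at its own best bandwidth
    p_values: dict[str, float]  # Brown–Forsythe vs best, at best's bandwidth
    eliminated: dict[str, bool]  # p < 0.05
    residuals: dict[str, np.ndarray]  # per-trial residuals at best's bandwidth


@dataclass
class ContinuumFit:
    """Localization of a response field on the T–G continuum."""

    alpha: float
    bandwidth: float
    mean_press: float
    press_residuals: np.ndarray
    alpha_grid: np.ndarray
    press_profile: np.ndarray  # per-alpha mean PRESS at that alpha's best bandwidth
    indeterminate: bool = False


class KernelBank:
    """Precomputed kernel weight stacks for repeated PRESS evaluation.

    Positions are fixed per unit while rates vary across shuffles and time
    bins, so the ``(n_sets, n_bandwidths, n, n)`` weight stack is built once
    and PRESS for any rate vector reduces to matrix–vector products.
    """

    def __init__(self, positions_list: Sequence[np.ndarray], bandwidths: np.ndarray, knn_fallback: int = 3):
        self.bandwidths = np.asarray(bandwidths, dtype=float)
        P = [np.asarray(p, dtype=float) for p in positions_list]
        n = P[0].shape[0]
        if any(p.shape != (n, 2) for p in P):
            raise ValueError("all position sets must be (n, 2) with equal n")
        if n < 2:
            raise ValueError("need at least 2 trials for leave-one-out fitting")
        self.n = n
        self.n_sets = len(P)
        d2 = np.empty((self.n_sets, n, n))
        for m, p in enumerate(P):
            diff = p[:, None, :] - p[None, :, :]
            d2[m] = np.einsum("ijk,ijk->ij", diff, diff)
        self.d2 = d2
        # (n_sets, nh, n, n); diagonal zeroed so leave-one-out sums exclude
        # the held-out trial exactly (no cancellation against the self weight)
        self.W = np.exp(-d2[:, None, :, :] / (2.0 * self.bandwidths[None, :, None, None] ** 2))
        di = np.arange(n)
        self.W[:, :, di, di] = 0.0
        self.den = self.W.sum(axis=-1)
        self._low = self.den < _EPS
        k = min(knn_fallback, n - 1)
        # neighbor indices by spatial distance, excluding self (h-independent)
        d2_self = d2.copy()
        idx = np.arange(n)
        d2_self[:, idx, idx] = np.inf
        self._knn = np.argpartition(d2_self, k - 1, axis=-1)[..., :k]  # (n_sets, n, k)

    def loo_predictions(self, rates: np.ndarray) -> np.ndarray:
        """Exact leave-one-out predictions, shape (n_sets, nh, n)."""
        r = np.asarray(rates, dtype=float)
        num = np.einsum("mhij,j->mhi", self.W, r)
        with np.errstate(invalid="ignore", divide="ignore"):
            pred = num / self.den
        if self._low.any():
            knn_mean = r[self._knn].mean(axis=-1)  # (n_sets, n)
            pred = np.where(self._low, np.broadcast_to(knn_mean[:, None, :], pred.shape), pred)
        return pred

    def mean_press(self, rates: np.ndarray) -> np.ndarray:
        """Mean squared LOO residual, shape (n_sets, nh)."""
        r = np.asarray(rates, dtype=float)
        res = r[None, None, :] - self.loo_predictions(r)
        return np.mean(res**2, axis=-1)

    def residuals(self, rates: np.ndarray, set_idx: int, h_idx: int) -> np.ndarray:
        r = np.asarray(rates, dtype=float)
        return r - self.loo_predictions(r)[set_idx, h_idx]

    def shuffle_mean_press_grid(self, rates_matrix: np.ndarray, set_idx: int) -> np.ndarray:
        """Mean PRESS for each permuted rate row at every bandwidth: (n_perm, nh)."""
        R = np.asarray(rates_matrix, dtype=float)
        W = self.W[set_idx]  # (nh, n, n)
        den = self.den[set_idx]  # (nh, n)
        num = np.einsum("hij,pj->phi", W, R)
        with np.errstate(invalid="ignore", divide="ignore"):
            pred = num / den[None, :, :]
        low = self._low[set_idx]
        if low.any():
            knn_mean = R[:, self._knn[set_idx]].mean(axis=-1)  # (n_perm, n)
            pred = np.where(low[None, :, :], knn_mean[:, None, :], pred)
        return np.mean((R[:, None, :] - pred) ** 2, axis=-1)

    def shuffle_mean_press(self, rates_matrix: np.ndarray, set_idx: int, h_idx: int) -> np.ndarray:
        """Mean PRESS for each row of permuted rates at one (set, bandwidth)."""
        R = np.asarray(rates_matrix, dtype=float)  # (n_perm, n)
        W = self.W[set_idx, h_idx]
        den = self.den[set_idx, h_idx]
        num = R @ W  # W symmetric, diagonal already zeroed
        with np.errstate(invalid="ignore", divide="ignore"):
            pred = num / den[None, :]
        low = self._low[set_idx]
        if low.any():
            knn_mean = R[:, self._knn[set_idx]].mean(axis=-1)  # (n_perm, n)
            pred = np.where(low[None, :], knn_mean, pred)
        return np.mean((R - pred) ** 2, axis=-1)


def kernel_fit_predict(
    positions: np.ndarray, rates: np.ndarray, query: np.ndarray, h: float, knn_fallback: int = 3
) -> np.ndarray:
    """Nadaraya–Watson prediction at query point(s).

    Falls back to the unweighted mean of the ``knn_fallback`` nearest
    training points where all kernel weights underflow.
    """
    X = np.atleast_2d(np.asarray(positions, dtype=float))
    r = np.asarray(rates, dtype=float)
    if len(X) == 0:
        raise ValueError("training set is empty")
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    Q = np.atleast_2d(np.asarray(query, dtype=float))
    diff = Q[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    W = np.exp(-d2 / (2.0 * h * h))
    den = W.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pred = (W @ r) / den
    low = den < _EPS
    if low.any():
        warnings.warn("kernel weights underflowed at some query points; using k-NN fallback")
        k = min(knn_fallback, len(X))
        nn = np.argpartition(d2, k - 1, axis=1)[:, :k]
        pred = np.where(low, r[nn].mean(axis=1), pred)
    return pred if np.asarray(query).ndim > 1 else float(pred[0])


def press_residuals(positions: np.ndarray, rates: np.ndarray, h: float) -> np.ndarray:
    """Exact leave-one-out residuals ``rᵢ − f₋ᵢ(xᵢ)`` at bandwidth ``h``."""
    bank = KernelBank([np.atleast_2d(positions)], np.asarray([h], dtype=float))
    return bank.residuals(rates, 0, 0)


def _tie_candidates(values: np.ndarray, scale: float) -> np.ndarray:
    """Indices tied with the minimum, up to float noise at the rate scale."""
    vmin = values.min()
    tol = 1e-9 * vmin + 1e-12 * scale
    return np.flatnonzero(values <= vmin + tol)


def _best_h(mp_row: np.ndarray, bandwidths: np.ndarray, scale: float = 0.0) -> int:
    """Index of the minimal mean PRESS; ties go to the smallest bandwidth."""
    return int(_tie_candidates(mp_row, scale)[0])  # grid ascending


class KernelResponseField(RegressorMixin, BaseEstimator):
    """Gaussian-kernel response-field regressor with PRESS bandwidth selection.

    Parameters
    ----------
    bandwidth : float or None
        Fixed kernel bandwidth in degrees.  If None, the bandwidth is
        selected from ``bandwidths`` by minimizing the mean squared
        leave-one-out (PRESS) residual; exact ties resolve to the
        smallest bandwidth.
    bandwidths : array-like or None
        Candidate grid (default 2–25° in 1° steps).
    knn_fallback : int
        Nearest-neighbor count for the underflow fallback.

    Attributes
    ----------
    bandwidth_ : float
        Selected (or fixed) bandwidth.
    press_residuals_ : ndarray
        Per-trial leave-one-out residuals at ``bandwidth_``.
    mean_press_ : float
        Mean squared PRESS residual at ``bandwidth_``.
    """

    def __init__(self, bandwidth: float | None = None, bandwidths=None, knn_fallback: int = 3):
        self.bandwidth = bandwidth
        self.bandwidths = bandwidths
        self.knn_fallback = knn_fallback

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=2)
        if X.shape[1] != 2:
            raise ValueError("positions must be 2D (n_samples, 2)")
        if self.bandwidth is not None:
            grid = np.asarray([float(self.bandwidth)])
        elif self.bandwidths is not None:
            grid = np.asarray(self.bandwidths, dtype=float)
        else:
            grid = default_bandwidths()
        bank = KernelBank([X], grid, self.knn_fallback)
        mp = bank.mean_press(y)[0]
        scale = float(np.mean(y**2))
        j = _best_h(mp, grid, scale)
        self.X_ = X
        self.y_ = y
        self.n_features_in_ = 2
        self.bandwidth_ = float(grid[j])
        self.press_residuals_ = bank.residuals(y, 0, j)
        self.mean_press_ = float(mp[j])
        self.press_curve_ = mp
        return self

    def predict(self, X):
        check_is_fitted(self, "bandwidth_")
        X = check_array(X)
        return np.atleast_1d(
            kernel_fit_predict(self.X_, self.y_, X, self.bandwidth_, self.knn_fallback)
        )


def fit_model(
    positions: np.ndarray, rates: np.ndarray, cfg: FitConfig | None = None, label: str = ""
) -> FitResult:
    """Fit one spatial model over the bandwidth grid; return the best fit."""
    cfg = cfg or FitConfig()
    est = KernelResponseField(bandwidths=cfg.bandwidths, knn_fallback=cfg.knn_fallback)
    est.fit(np.atleast_2d(positions), np.asarray(rates, dtype=float))
    return FitResult(
        model_label=label,
        bandwidth=est.bandwidth_,
        press_residuals=est.press_residuals_,
        mean_press=est.mean_press_,
    )


def brown_forsythe(group_a, group_b) -> tuple[float, float]:
    """Brown–Forsythe (Levene, median-centered) test between two groups.

    Operates on absolute deviations from each group's median; p from the
    upper tail of the one-way F/W statistic.  If neither group has any
    spread about its median the test is degenerate and ``(0.0, 1.0)`` is
    returned by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    za = np.abs(a - np.median(a))
    zb = np.abs(b - np.median(b))
    if np.all(za == 0) and np.all(zb == 0):
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.levene(a, b, center="median")
    if not np.isfinite(stat):
        return 0.0, 1.0
    return float(stat), float(p)


def compare_models(
    positions_by_model: Mapping[str, np.ndarray],
    rates: np.ndarray,
    cfg: FitConfig | None = None,
) -> ModelComparison:
    """Rank candidate spatial models by PRESS and test competitors vs best.

    Every model is fit over the full bandwidth grid; the model with the
    lowest mean PRESS (at its own best bandwidth) is "best".  Each
    competitor's per-trial residuals, recomputed at the best model's
    bandwidth, are compared with the best model's residuals by a
    Brown–Forsythe test; competitors with p < 0.05 are flagged eliminated.
    """
    cfg = cfg or FitConfig()
    names = list(positions_by_model)
    if len(names) == 0:
        raise ValueError("no candidate models supplied")
    bank = KernelBank([positions_by_model[m] for m in names], cfg.bandwidths, cfg.knn_fallback)
    r = np.asarray(rates, dtype=float)
    mp = bank.mean_press(r)  # (n_models, nh)
    scale = float(np.mean(r**2))
    best_h_idx = [_best_h(row, cfg.bandwidths, scale) for row in mp]
    best_mp = {m: float(mp[i, best_h_idx[i]]) for i, m in enumerate(names)}
    i_best = int(np.argmin([best_mp[m] for m in names]))
    j_star = best_h_idx[i_best]
    residuals = {m: bank.residuals(r, i, j_star) for i, m in enumerate(names)}
    best = names[i_best]
    p_values: dict[str, float] = {}
    for m in names:
        if m == best:
            p_values[m] = 1.0
        else:
            _, p = brown_forsythe(residuals[m], residuals[best])
            p_values[m] = p
    eliminated = {m: (m != best and p_values[m] < 0.05) for m in names}
    return ModelComparison(
        best_label=best,
        bandwidth=float(cfg.bandwidths[j_star]),
        mean_press=best_mp,
        p_values=p_values,
        eliminated=eliminated,
        residuals=residuals,
    )


def _best_alpha_index(per_alpha_mp: np.ndarray, alpha_grid: np.ndarray, scale: float = 0.0) -> int:
    """Minimal-PRESS α; ties resolve to the α nearest 0, then the smaller
    (target-side) α."""
    cand = _tie_candidates(per_alpha_mp, scale)
    order = sorted(cand, key=lambda i: (abs(alpha_grid[i]), alpha_grid[i]))
    return int(order[0])


class TGContinuumLocalizer(BaseEstimator):
    """Localize a response field on the target–gaze continuum.

    ``fit`` takes ``X`` of shape ``(n, 4)`` holding per-trial continuum
    anchors ``[te_x, te_y, ge_x, ge_y]`` (eye-centered target and future-
    gaze positions) and ``y`` the per-trial firing rates.  At every α on
    the grid the positions ``Te + α(Ge − Te)`` are fit over the full
    bandwidth grid, and the α with minimal mean PRESS wins; exact ties
    resolve to the α nearest 0 (target side).

    Attributes
    ----------
    alpha_ : float
        Best continuum step (0 = target code, 1 = gaze code).
    bandwidth_ : float
        Bandwidth of the winning fit.
    mean_press_ : float
    press_profile_ : ndarray
        Per-α mean PRESS at each α's best bandwidth.
    indeterminate_ : bool
        True when Te = Ge on every trial (the continuum collapses and α
        carries no information; ``alpha_`` is reported as 0).
    """

    def __init__(self, alpha_grid=None, bandwidths=None, knn_fallback: int = 3):
        self.alpha_grid = alpha_grid
        self.bandwidths = bandwidths
        self.knn_fallback = knn_fallback

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=3)
        if X.shape[1] != 4:
            raise ValueError("X must be (n, 4): columns te_x, te_y, ge_x, ge_y")
        grid_a = np.asarray(self.alpha_grid, dtype=float) if self.alpha_grid is not None else default_alpha_grid()
        grid_h = np.asarray(self.bandwidths, dtype=float) if self.bandwidths is not None else default_bandwidths()
        te, ge = X[:, :2], X[:, 2:]
        self.indeterminate_ = bool(np.allclose(te, ge))
        positions = [te + a * (ge - te) for a in grid_a]
        bank = KernelBank(positions, grid_h, self.knn_fallback)
        mp = bank.mean_press(y)  # (n_alpha, nh)
        scale = float(np.mean(y**2))
        hsel = np.array([_best_h(row, grid_h, scale) for row in mp])
        profile = mp[np.arange(len(grid_a)), hsel]
        i = _best_alpha_index(profile, grid_a, scale)
        if self.indeterminate_:
            i = int(np.flatnonzero(np.isclose(grid_a, 0.0))[0])
        j = int(hsel[i])
        self.alpha_grid_ = grid_a
        self.alpha_ = float(grid_a[i])
        self.bandwidth_ = float(grid_h[j])
        self.mean_press_ = float(mp[i, j])
        self.press_profile_ = profile
        self.press_residuals_ = bank.residuals(y, i, j)
        return self

    def fit_alpha(self, X, y) -> float:
        return self.fit(X, y).alpha_


def fit_tg_continuum(
    te: np.ndarray, ge: np.ndarray, rates: np.ndarray, cfg: FitConfig | None = None
) -> ContinuumFit:
    """Functional wrapper around :class:`TGContinuumLocalizer`."""
    cfg = cfg or FitConfig()
    loc = TGContinuumLocalizer(
        alpha_grid=cfg.alpha_grid, bandwidths=cfg.bandwidths, knn_fallback=cfg.knn_fallback
    )
    X = np.hstack([np.atleast_2d(te), np.atleast_2d(ge)])
    loc.fit(X, np.asarray(rates, dtype=float))
    return ContinuumFit(
        alpha=loc.alpha_,
        bandwidth=loc.bandwidth_,
        mean_press=loc.mean_press_,
        press_residuals=loc.press_residuals_,
        alpha_grid=loc.alpha_grid_,
        press_profile=loc.press_profile_,
        indeterminate=loc.indeterminate_,
    )
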