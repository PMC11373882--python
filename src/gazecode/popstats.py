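"""Population-level statistics for continuum-fit distributions.

These summarize the best-fit α values of a population of units: location
tests against the pure target (α = 0) and gaze (α = 1) codes, group
comparisons (rank and variance), paired visual-to-motor shifts with
slope/elevation comparison between groups, two-component Gaussian mixture
fits for bimodality, rank correlations for site matching, and the
across-unit model comparison that mirrors the per-unit PRESS ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.proportion import proportions_ztest as _sm_proportions_ztest

from .rf import brown_forsythe

__all__ = [
    "DistributionSummary",
    "Mixture2",
    "PairedShift",
    "distribution_summary",
    "compare_groups",
    "proportions_ztest",
    "paired_vm_shift",
    "mixture2_fit",
    "spearman_corr",
    "population_model_comparison",
]


@dataclass
class DistributionSummary:
    n: int
    mean: float
    median: float
    p_vs_T: float  # one-sample signed-rank test against 0 (target code)
    p_vs_G: float  # against 1 (gaze code)
    fraction_below_half: float


@dataclass
class Mixture2:
    """Two-component 1D Gaussian mixture, components sorted by mean."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    log_likelihood: float


@dataclass
class PairedShift:
    n: int
    median_visual: float
    median_motor: float
    p_paired: float
    slope: float
    slope_se: float
    slope_diff_p: float | None = None
    elevation_diff_p: float | None = None


def signed_rank_p(values: Sequence[float], mu: float = 0.0) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p against ``mu``.

    Exact for n ≤ 25 without ties or zero differences, otherwise the
    normal approximation with continuity correction.  All-zero differences
    are degenerate and return p = 1.
    """
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=(method == "approx"))
    return float(res.pvalue)


def distribution_summary(alphas: Sequence[float]) -> DistributionSummary:
    """Location summary of a best-fit α distribution."""
    a = np.asarray(alphas, dtype=float)
    if len(a) < 1:
        raise ValueError("need at least one value")
    return DistributionSummary(
        n=len(a),
        mean=float(np.mean(a)),
        median=float(np.median(a)),
        p_vs_T=signed_rank_p(a, 0.0),
        p_vs_G=signed_rank_p(a, 1.0),
        fraction_below_half=float(np.mean(a < 0.5)),
    )


def compare_groups(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Two-sided Mann–Whitney p, variance-ratio F = var(a)/var(b), and its
    two-sided F-test p.  Zero variance in both groups is degenerate
    (F = 1, p = 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    mw_p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return mw_p, 1.0, 1.0
    if vb == 0:
        return mw_p, float("inf"), 0.0
    F = va / vb
    dist = stats.f(len(a) - 1, len(b) - 1)
    var_p = float(2 * min(dist.cdf(F), dist.sf(F)))
    return mw_p, float(F), min(var_p, 1.0)


def proportions_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test (two-sided)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be at least 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    z, p = _sm_proportions_ztest([k1, k2], [n1, n2])
    return float(z), float(p)


def paired_vm_shift(
    visual: Sequence[float],
    motor: Sequence[float],
    other: tuple[Sequence[float], Sequence[float]] | None = None,
) -> PairedShift:
    """Within-unit visual-to-motor shift along the continuum.

    Signed-rank test on motor − visual, marginal medians, and the least-
    squares slope of motor on visual.  When a second (visual, motor) group
    is supplied, the regression lines are compared: an F-test for a common
    slope (interaction term), then — assuming the common slope — an F-test
    for equal elevations (intercepts), in the usual analysis-of-covariance
    sequence.
    """
    v = np.asarray(visual, dtype=float)
    m = np.asarray(motor, dtype=float)
    if len(v) != len(m) or len(v) < 3:
        raise ValueError("need at least 3 (visual, motor) pairs")
    p_paired = signed_rank_p(m - v, 0.0)
    fit = sm.OLS(m, sm.add_constant(v)).fit()
    slope, slope_se = float(fit.params[1]), float(fit.bse[1])
    slope_diff_p = elevation_diff_p = None
    if other is not None:
        v2 = np.asarray(other[0], dtype=float)
        m2 = np.asarray(other[1], dtype=float)
        x = np.concatenate([v, v2])
        y = np.concatenate([m, m2])
        g = np.concatenate([np.zeros(len(v)), np.ones(len(v2))])
        X_full = sm.add_constant(np.column_stack([x, g, x * g]))
        X_slope = sm.add_constant(np.column_stack([x, g]))
        X_pool = sm.add_constant(x)
        full = sm.OLS(y, X_full).fit()
        common = sm.OLS(y, X_slope).fit()
        pooled = sm.OLS(y, X_pool).fit()
        def _nested_f_p(restricted, full_model):
            # degenerate when the extra term explains (numerically) nothing
            with np.errstate(invalid="ignore", divide="ignore"):
                f_stat, p, _ = full_model.compare_f_test(restricted)
            if not np.isfinite(p) or f_stat <= 0:
                return 1.0
            return float(p)

        slope_diff_p = _nested_f_p(common, full)
        elevation_diff_p = _nested_f_p(pooled, common)
    return PairedShift(
        n=len(v),
        median_visual=float(np.median(v)),
        median_motor=float(np.median(m)),
        p_paired=p_paired,
        slope=slope,
        slope_se=slope_se,
        slope_diff_p=slope_diff_p,
        elevation_diff_p=elevation_diff_p,
    )


def mixture2_fit(alphas: Sequence[float], seed: int = 0) -> Mixture2:
    """Two-component Gaussian mixture by EM with 10 random restarts.

    Components are returned sorted by mean.  Degenerate input (all values
    equal) collapses both components onto that value with SDs floored at
    10⁻³.
    """
    a = np.asarray(alphas, dtype=float)
    if len(a) < 4:
        raise ValueError("need at least 4 values for a 2-component fit")
    if np.ptp(a) == 0:
        v = float(a[0])
        ll = float(np.sum(stats.norm.logpdf(a, v, 1e-3)))
        return Mixture2(weights=(0.5, 0.5), means=(v, v), sds=(1e-3, 1e-3), log_likelihood=ll)
    gm = GaussianMixture(
        n_components=2, n_init=10, random_state=int(seed), tol=1e-8, max_iter=500, reg_covar=1e-9
    ).fit(a.reshape(-1, 1))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    order = np.argsort(means)
    w = gm.weights_[order]
    return Mixture2(
        weights=(float(w[0]), float(w[1])),
        means=(float(means[order][0]), float(means[order][1])),
        sds=(max(float(sds[order][0]), 1e-3), max(float(sds[order][1]), 1e-3)),
        log_likelihood=float(gm.score(a.reshape(-1, 1)) * len(a)),
    )


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with two-sided p (midranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired values")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def population_model_comparison(
    mean_press_by_model: Mapping[str, Sequence[float]]
) -> tuple[str, dict[str, float]]:
    """Across-unit spatial-model comparison.

    Each model contributes its per-unit mean PRESS values; the model with
    the lowest across-unit mean is best (p = 1 by convention) and every
    other model is tested against it with a Brown–Forsythe test.
    """
    if len(mean_press_by_model) < 1:
        raise ValueError("need at least one model")
    means = {m: float(np.mean(np.asarray(v, dtype=float))) for m, v in mean_press_by_model.items()}
    best = min(means, key=means.get)
    best_vals = np.asarray(mean_press_by_model[best], dtype=float)
    if len(best_vals) < 2:
        raise ValueError("need at least 2 units")
    p_values = {}
    for m, v in mean_press_by_model.items():
        if m == best:
            p_values[m] = 1.0
        else:
            v = np.asarray(v, dtype=float)
            p_values[m] = 1.0 if np.array_equal(v, best_vals) else brown_forsythe(v, best_vals)[1]
    return best, p_values
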