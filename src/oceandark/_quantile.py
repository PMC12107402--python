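"""Median (tau = 0.5) regression with rank-score-inversion confidence intervals.

The slope CI inverts the quantile regression rank-score test (iid error
variant): for a hypothesized slope b, the intercept-only tau-quantile of the
partial residuals y - b*x yields regression rank scores, and the normalized
score statistic T(b) is monotonically nonincreasing in b.  The level-alpha CI
is the set of b with |T(b)| below the normal critical value; its endpoints
are located by bisection.  Ties at the fitted quantile receive fractional
(midrank) scores.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

__all__ = ["median_fit", "rank_ci", "quantile_trend_core"]

_TAU = 0.5


def median_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Median-regression point estimate (intercept, slope).

    Uses statsmodels QuantReg; exactly collinear input short-circuits to the
    interpolating line (IRLS is fragile when every residual is zero).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    # exact-collinearity short circuit
    A = np.column_stack([np.ones_like(x), x])
    beta, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    scale = max(np.ptp(y), 1e-12)
    if np.max(np.abs(resid)) <= 1e-10 * scale:
        return float(beta[0]), float(beta[1])
    from statsmodels.regression.quantile_regression import QuantReg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = QuantReg(y, A).fit(q=_TAU, max_iter=2000)
    return float(res.params[0]), float(res.params[1])


def _rank_statistic(x_c: np.ndarray, z: np.ndarray, denom: float) -> float:
    """Normalized rank-score statistic for H0 at the given partial residuals.

    x_c is the centered covariate; z = y - b*x.  Scores are a_i - (1 - tau)
    with a_i the intercept-only regression rank scores (fractional at ties).
    """
    n = len(z)
    m = np.median(z)
    above = z > m
    below = z < m
    at = ~(above | below)
    a = np.zeros(n)
    a[above] = 1.0
    k_at = int(at.sum())
    if k_at:
        # distribute so that sum(a) = (1 - tau) * n
        target = (1.0 - _TAU) * n - above.sum()
        a[at] = np.clip(target / k_at, 0.0, 1.0)
    s = a - (1.0 - _TAU)
    return float(np.dot(x_c, s) / denom)


def rank_ci(
    x: np.ndarray, y: np.ndarray, slope_hat: float, level: float = 0.95
) -> tuple[float, float]:
    """Rank-inversion CI for the slope at the given confidence level."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_c = x - x.mean()
    ssx = float(np.dot(x_c, x_c))
    if ssx <= 0:
        return (-np.inf, np.inf)
    denom = np.sqrt(_TAU * (1.0 - _TAU) * ssx)
    crit = stats.norm.ppf(0.5 + level / 2.0)

    def t_of(b: float) -> float:
        return _rank_statistic(x_c, y - b * x, denom)

    # scale for bracketing: data-driven slope magnitude
    scale = max(np.ptp(y) / max(np.ptp(x), 1e-12), abs(slope_hat), 1e-12)

    def bracket(target: float, direction: int) -> tuple[float, float]:
        """Expand from slope_hat until T crosses below/above target."""
        step = scale
        b0 = slope_hat
        for _ in range(80):
            b1 = slope_hat + direction * step
            t1 = t_of(b1)
            if (direction > 0 and t1 < target) or (direction < 0 and t1 > target):
                return (min(b0, b1), max(b0, b1))
            b0 = b1
            step *= 2.0
        return (min(b0, slope_hat + direction * step), max(b0, slope_hat + direction * step))

    def bisect(lo: float, hi: float, target: float) -> float:
        """T is nonincreasing; find b where T crosses ``target``."""
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if t_of(mid) > target:
                lo = mid
            else:
                hi = mid
            if hi - lo <= 1e-12 + 1e-9 * scale:
                break
        return 0.5 * (lo + hi)

    # upper endpoint: T crosses -crit going up in b; lower: +crit going down
    lo_u, hi_u = bracket(-crit, +1)
    upper = bisect(lo_u, hi_u, -crit)
    lo_l, hi_l = bracket(+crit, -1)
    lower = bisect(lo_l, hi_l, +crit)
    if lower > upper:  # degenerate/discrete corner: collapse onto estimate
        lower, upper = min(lower, slope_hat), max(upper, slope_hat)
    return (float(lower), float(upper))


def quantile_trend_core(
    fitted: np.ndarray, years: np.ndarray, level: float = 0.95
) -> tuple[float, float, float, float]:
    """Median-regression trend of fitted values against calendar years.

    Returns (slope, intercept, ci_low, ci_high); the intercept is at year 0.
    Degenerate all-equal input yields a zero slope whose CI contains zero.
    """
    years = np.asarray(years, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if len(fitted) < 3:
        raise ValueError("need at least 3 points for a trend")
    if np.ptp(fitted) < 1e-14:
        return (0.0, float(fitted[0]), 0.0, 0.0)
    intercept, slope = median_fit(years, fitted)
    ci_low, ci_high = rank_ci(years, fitted, slope, level=level)
    # the point estimate always lies inside its own interval
    ci_low = min(ci_low, slope)
    ci_high = max(ci_high, slope)
    return (slope, intercept, ci_low, ci_high)
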