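"""Conditional-sum-of-squares ARIMA(p,1,q)+drift engine for short annual series.

Per-pixel trend mapping needs on the order of millions of ARIMA fits; full
state-space maximum likelihood is two orders of magnitude too slow for that.
This module fits ARMA(p,q) models with a constant (drift on the undifferenced
scale) to the first-differenced series by conditional sum of squares:
pure-AR models solve exactly by least squares, mixed models by bounded
least squares on the residual recursion.  AIC uses the Gaussian CSS
likelihood.  Tests cross-check fitted values and order selection against the
statsmodels state-space implementation, which remains available as the
``statespace`` engine in :mod:`oceandark.trend`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

_LOG_GUARD = 1e-30  # CSS floor: a deterministic series fits exactly


@dataclass
class CssArmaFit:
    order: tuple[int, int, int]   # (p, 1, q)
    const: float                  # intercept of the differenced-scale model
    ar: np.ndarray
    ma: np.ndarray
    sigma2: float
    aic: float
    converged: bool

    @property
    def mean_diff(self) -> float:
        """Unconditional mean of the differenced series implied by the fit
        (the drift of the level series)."""
        denom = 1.0 - float(np.sum(self.ar))
        return self.const / denom if abs(denom) > 1e-9 else self.const


# One-step predictions/residuals of w_t under
#   w_t = const + sum_i ar_i w_{t-i} + sum_j ma_j e_{t-j} + e_t,
# presample w lags replaced by the unconditional mean, presample e = 0.
def _recursion_py(w, const, ar, ma):  # pragma: no cover - numba path preferred
    p, q = len(ar), len(ma)
    m = len(w)
    denom = 1.0 - float(np.sum(ar))
    if abs(denom) > 1e-9:
        mu = const / denom
    else:
        mu = float(np.mean(w)) if m else 0.0
    e = np.zeros(m)
    pred = np.empty(m)
    for t in range(m):
        ph = const
        for i in range(p):
            ph += ar[i] * (w[t - 1 - i] if t - 1 - i >= 0 else mu)
        for j in range(q):
            if t - 1 - j >= 0:
                ph += ma[j] * e[t - 1 - j]
        pred[t] = ph
        e[t] = w[t] - ph
    return pred, e


try:  # tight loop: jit-compiled when numba is available
    import numba

    @numba.njit(cache=True)
    def _recursion_nb(w, const, ar, ma):  # pragma: no cover - thin jit shim
        p, q = len(ar), len(ma)
        m = len(w)
        denom = 1.0 - np.sum(ar)
        if abs(denom) > 1e-9:
            mu = const / denom
        elif m > 0:
            mu = np.mean(w)
        else:
            mu = 0.0
        e = np.zeros(m)
        pred = np.empty(m)
        for t in range(m):
            ph = const
            for i in range(p):
                if t - 1 - i >= 0:
                    ph += ar[i] * w[t - 1 - i]
                else:
                    ph += ar[i] * mu
            for j in range(q):
                if t - 1 - j >= 0:
                    ph += ma[j] * e[t - 1 - j]
            pred[t] = ph
            e[t] = w[t] - ph
        return pred, e

    def _recursion(w, const, ar, ma):
        return _recursion_nb(np.ascontiguousarray(w, dtype=np.float64), float(const),
                             np.ascontiguousarray(ar, dtype=np.float64),
                             np.ascontiguousarray(ma, dtype=np.float64))

    @numba.njit(cache=True)
    def _css_lm_nb(w, p, q, x0):  # pragma: no cover - thin jit shim
        """Levenberg-Marquardt on the CSS residual recursion.

        Parameter vector x = [const, ar..., ma...]; AR/MA coefficients are
        box-clipped to [-1.5, 1.5].  Returns (x, css, converged).
        """
        m = len(w)
        n_res = m - p
        k = 1 + p + q

        def resid(x):
            _, e = _recursion_nb(w, x[0], x[1 : 1 + p], x[1 + p :])
            return e[p:]

        x = x0.copy()
        r = resid(x)
        css = r @ r
        lam = 1e-3
        converged = False
        J = np.empty((n_res, k))
        for _ in range(80):
            for j in range(k):
                h = 1e-7 * (1.0 + abs(x[j]))
                xj = x.copy()
                xj[j] += h
                J[:, j] = (resid(xj) - r) / h
            A = J.T @ J
            g = J.T @ r
            improved = False
            for _ in range(12):
                Ad = A.copy()
                for j in range(k):
                    Ad[j, j] += lam * (A[j, j] + 1e-12)
                dx = np.linalg.solve(Ad, -g)
                xt = x + dx
                for j in range(1, k):
                    if xt[j] > 1.5:
                        xt[j] = 1.5
                    elif xt[j] < -1.5:
                        xt[j] = -1.5
                rt = resid(xt)
                ct = rt @ rt
                if ct < css:
                    x, r, css = xt, rt, ct
                    lam = max(lam * 0.3, 1e-10)
                    improved = True
                    break
                lam *= 8.0
                if lam > 1e8:
                    break
            if not improved:
                converged = True
                break
            if np.sqrt(dx @ dx) < 1e-10 * (1.0 + np.sqrt(x @ x)):
                converged = True
                break
        return x, css, converged

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _recursion = _recursion_py
    _HAVE_NUMBA = False


def _hannan_rissanen_start(w: np.ndarray, p: int, q: int) -> np.ndarray | None:
    """Two-stage Hannan-Rissanen starting values for ARMA(p,q)+constant:
    residuals of a long-AR pre-fit enter an OLS with the ARMA design."""
    m = len(w)
    h = min(4, max((m - 1) // 3, 1))
    try:
        pre = fit_css(w, h, 0)
    except (ValueError, np.linalg.LinAlgError):
        return None
    _, e = _recursion(w, pre.const, pre.ar, np.zeros(0))
    s = max(p, q)
    if m - s < p + q + 2:
        return None
    X = np.ones((m - s, 1 + p + q))
    for i in range(p):
        X[:, 1 + i] = w[s - 1 - i : m - 1 - i]
    for j in range(q):
        X[:, 1 + p + j] = e[s - 1 - j : m - 1 - j]
    try:
        beta, *_ = np.linalg.lstsq(X, w[s:], rcond=None)
    except np.linalg.LinAlgError:
        return None
    beta[1:] = np.clip(beta[1:], -1.4, 1.4)
    return beta


def fit_css(w: np.ndarray, p: int, q: int) -> CssArmaFit:
    """Fit ARMA(p, q) + constant to the differenced series ``w`` by CSS.

    The sum of squares conditions on the first ``p`` observations (presample
    residuals zero).  AIC = n_eff * log(css / n_eff) + 2k with
    n_eff = len(w) - p and k = p + q + 2 (constant + innovation variance).
    """
    w = np.asarray(w, dtype=float)
    m = len(w)
    if m - p < p + q + 2:
        raise ValueError("series too short for the requested order")
    k = p + q + 2
    n_eff = m - p

    if np.ptp(w) < 1e-12:  # constant differences: exact degenerate fit
        const = float(w.mean()) if m else 0.0
        return CssArmaFit((p, 1, q), const, np.zeros(p), np.zeros(q),
                          0.0, n_eff * np.log(_LOG_GUARD) + 2 * k, True)

    if q == 0:
        # pure AR + constant: exact linear least squares on the lagged design
        X = np.ones((m - p, p + 1))
        for i in range(p):
            X[:, 1 + i] = w[p - 1 - i : m - 1 - i]
        y = w[p:]
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        css = float(resid @ resid)
        const, ar, ma = float(beta[0]), beta[1:].copy(), np.zeros(0)
        converged = True
    else:
        x0 = np.zeros(1 + p + q)
        x0[0] = float(w.mean())
        if p:
            try:
                pre = fit_css(w, p, 0)
                x0[0] = pre.const
                x0[1 : 1 + p] = np.clip(pre.ar, -0.9, 0.9)
            except ValueError:
                pass
        starts = [x0]
        hr = _hannan_rissanen_start(w, p, q)
        if hr is not None:
            starts.append(hr)

        if _HAVE_NUMBA:
            best_x, best_css, converged = None, np.inf, False
            for s in starts:
                xs, css_s, conv_s = _css_lm_nb(np.ascontiguousarray(w), p, q,
                                               np.ascontiguousarray(s))
                if css_s < best_css:
                    best_x, best_css, converged = xs, float(css_s), conv_s
            xs, css = best_x, best_css
            const, ar, ma = float(xs[0]), xs[1 : 1 + p].copy(), xs[1 + p :].copy()
        else:  # pragma: no cover - scipy fallback
            def fun(theta: np.ndarray) -> np.ndarray:
                _, e = _recursion(w, theta[0], theta[1 : 1 + p], theta[1 + p :])
                return e[p:]

            lb = np.concatenate([[-np.inf], -1.5 * np.ones(p + q)])
            ub = np.concatenate([[np.inf], 1.5 * np.ones(p + q)])
            sol = least_squares(fun, x0, bounds=(lb, ub), method="trf",
                                xtol=1e-9, ftol=1e-9, max_nfev=250)
            const = float(sol.x[0])
            ar = sol.x[1 : 1 + p].copy()
            ma = sol.x[1 + p :].copy()
            css = float(2 * sol.cost)
            converged = bool(sol.success)

    sigma2 = css / n_eff
    aic = n_eff * np.log(max(sigma2, _LOG_GUARD)) + 2 * k
    return CssArmaFit((p, 1, q), const, ar, ma, sigma2, aic, converged)


def select_order_css(w: np.ndarray, orders: list[tuple[int, int]]) -> CssArmaFit:
    """Grid-search (p, q) by CSS AIC; ties break toward the earliest listed
    order, so iterate by ascending p+q for parsimony."""
    best: CssArmaFit | None = None
    for p, q in orders:
        try:
            fit = fit_css(w, p, q)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not np.isfinite(fit.aic):
            continue
        if best is None or fit.aic < best.aic - 1e-12:
            best = fit
    if best is None:
        best = fit_css(w, 0, 0)
    return best


def fitted_levels(y: np.ndarray, fit: CssArmaFit) -> np.ndarray:
    """In-sample one-step fitted values on the original (level) scale.

    fitted_t = y_{t-1} + what_t for t >= 1, where what_t is the one-step
    prediction of the t-th difference; fitted_0 = y_0 (no information exists
    before the first observation once a difference is taken).
    """
    y = np.asarray(y, dtype=float)
    w = np.diff(y)
    pred_w, _ = _recursion(w, fit.const, fit.ar, fit.ma)
    fitted = np.empty_like(y)
    fitted[0] = y[0]
    fitted[1:] = y[:-1] + pred_w
    return fitted
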