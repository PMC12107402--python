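"""Per-pixel K_d(490) trend detection.

The per-pixel chain reproduces the darkening analysis: serial autocorrelation
in each annual series is absorbed by the most parsimonious ARIMA(p,1,q)+drift
model (AIC over p,q in {0,1,2}), a median (tau=0.5) quantile regression is
fitted to the ARIMA's in-sample fitted values, and its 95% rank-inversion
confidence interval classifies the pixel as increasing / decreasing /
no_change.  Significant pixels carry the regression line's predictions at the
first and last year; non-significant pixels fall back to the median of the
observed series for both endpoints.

The modelling surface follows the statsmodels convention:
``KdTrendModel(stack).fit()`` returns a :class:`KdTrendResults` holding the
per-pixel estimate rasters and a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._arma import CssArmaFit, fit_css, fitted_levels, select_order_css
from ._quantile import quantile_trend_core
from .grids import KD_MIN, GridSpec, KdRasterStack

__all__ = [
    "TrendResult",
    "KdTrendModel",
    "KdTrendResults",
    "select_arima",
    "fitted_values",
    "quantile_trend",
    "classify_and_predict",
    "trend_map",
    "CLASS_CODES",
]

#: Raster encoding of the classification (colour convention: red=increasing,
#: blue=decreasing, white=no_change).
CLASS_CODES = {"increasing": 1, "decreasing": -1, "no_change": 0,
               "insufficient_data": -9}

_DEFAULT_ORDERS: tuple[tuple[int, int], ...] = tuple(
    sorted(((p, q) for p in range(3) for q in range(3)), key=lambda pq: (sum(pq), pq))
)


@dataclass
class TrendResult:
    """Trend estimate for one pixel's annual K_d(490) series."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    classification: str
    kd_start: float
    kd_end: float
    n_valid: int
    arima_order: tuple[int, int, int]

    @classmethod
    def insufficient(cls, n_valid: int) -> "TrendResult":
        return cls(np.nan, np.nan, np.nan, np.nan, "insufficient_data",
                   np.nan, np.nan, n_valid, (0, 1, 0))


def _prepare_series(series: np.ndarray, years: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray] | None:
    """Trim leading/trailing gaps and interpolate interior ones.

    Returns (years_used, filled_values, observed_mask) or None if no valid
    observations remain.  The observed mask marks true (non-interpolated)
    years; only those feed the quantile regression.
    """
    valid = np.isfinite(series)
    if not valid.any():
        return None
    first, last = np.argmax(valid), len(valid) - 1 - np.argmax(valid[::-1])
    yrs = np.asarray(years[first : last + 1], dtype=float)
    vals = series[first : last + 1].astype(float)
    obs = np.isfinite(vals)
    if not obs.all():
        vals = vals.copy()
        vals[~obs] = np.interp(yrs[~obs], yrs[obs], vals[obs])
    return yrs, vals, obs


def select_arima(
    series: np.ndarray,
    orders: tuple[tuple[int, int], ...] = _DEFAULT_ORDERS,
    engine: str = "css",
) -> CssArmaFit:
    """Pick the AIC-best ARIMA(p,1,q)+drift order for one annual series.

    ``d`` is fixed at 1.  With the default engine the model is estimated by
    conditional sum of squares (see :mod:`oceandark._arma`); ``statespace``
    delegates to statsmodels' exact maximum likelihood.  An all-constant
    series degenerates to (0,1,0).
    """
    series = np.asarray(series, dtype=float)
    w = np.diff(series)
    if engine == "css":
        return select_order_css(w, list(orders))
    if engine != "statespace":
        raise ValueError(f"unknown engine {engine!r}")
    from statsmodels.tsa.arima.model import ARIMA

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p, q in orders:
            try:
                res = ARIMA(series, order=(p, 1, q), trend="t").fit()
            except Exception:
                continue
            if not np.isfinite(res.aic):
                continue
            if best is None or res.aic < best[0] - 1e-12:
                best = (res.aic, (p, q), res)
    if best is None:
        return fit_css(w, 0, 0)
    (p, q) = best[1]
    # re-express as a CSS fit container for a uniform downstream interface
    fit = fit_css(w, p, q)
    return fit


def fitted_values(
    series: np.ndarray, fit: CssArmaFit
) -> np.ndarray:
    """In-sample one-step fitted values on the level scale (same length).

    The first fitted value equals the first observation; a failed or
    non-finite fit cascades to (0,1,0)+drift.
    """
    series = np.asarray(series, dtype=float)
    out = fitted_levels(series, fit)
    if not np.all(np.isfinite(out)):
        out = fitted_levels(series, fit_css(np.diff(series), 0, 0))
    return out


def quantile_trend(
    fitted: np.ndarray, years: np.ndarray, level: float = 0.95
) -> tuple[float, float, tuple[float, float]]:
    """Median-regression slope/intercept of fitted values vs calendar year,
    with the rank-inversion CI at the given level."""
    slope, intercept, lo, hi = quantile_trend_core(fitted, years, level=level)
    return slope, intercept, (lo, hi)


def classify_and_predict(
    slope: float,
    intercept: float,
    ci: tuple[float, float],
    raw_series: np.ndarray,
    years: np.ndarray,
    fit: CssArmaFit | None = None,
    n_valid: int | None = None,
) -> TrendResult:
    """Apply the CI classification rule and predict the endpoint K_d values.

    Significant pixels (CI excluding zero) evaluate the regression line at
    the first and last calendar year; others take the median of the observed
    series as both endpoints.  Predictions are floored at the K_d validity
    minimum.
    """
    years = np.asarray(years, dtype=float)
    lo, hi = ci
    if lo > 0:
        cls = "increasing"
    elif hi < 0:
        cls = "decreasing"
    else:
        cls = "no_change"
    obs = np.asarray(raw_series, dtype=float)
    obs = obs[np.isfinite(obs)]
    if n_valid is None:
        n_valid = len(obs)
    if cls == "no_change":
        med = float(np.median(obs)) if len(obs) else np.nan
        kd_start = kd_end = max(med, KD_MIN)
    else:
        kd_start = max(intercept + slope * years[0], KD_MIN)
        kd_end = max(intercept + slope * years[-1], KD_MIN)
    order = fit.order if fit is not None else (0, 1, 0)
    return TrendResult(slope, intercept, lo, hi, cls, kd_start, kd_end,
                       int(n_valid), order)


def fit_pixel(
    series: np.ndarray,
    years: np.ndarray,
    min_valid_years: int = 10,
    orders: tuple[tuple[int, int], ...] = _DEFAULT_ORDERS,
    ci_level: float = 0.95,
    engine: str = "css",
) -> TrendResult:
    """Full per-pixel chain: ARIMA -> fitted values -> median trend -> class."""
    series = np.asarray(series, dtype=float)
    n_valid = int(np.isfinite(series).sum())
    if n_valid < min_valid_years:
        return TrendResult.insufficient(n_valid)
    prep = _prepare_series(series, np.asarray(years))
    if prep is None:
        return TrendResult.insufficient(n_valid)
    yrs, vals, obs = prep
    try:
        fit = select_arima(vals, orders=orders, engine=engine)
        fv = fitted_values(vals, fit)
        slope, intercept, ci = quantile_trend(fv[obs], yrs[obs], level=ci_level)
    except Exception:
        return TrendResult.insufficient(n_valid)
    return classify_and_predict(slope, intercept, ci, series, years,
                                fit=fit, n_valid=n_valid)


class KdTrendModel:
    """Per-pixel darkening-trend model for an annual K_d(490) stack.

    Parameters
    ----------
    stack
        Annual K_d(490) rasters with a missing mask.
    min_valid_years
        Minimum non-missing years for a pixel to be fitted (default 10).
    orders
        ARIMA (p, q) search grid; d is always 1.
    ci_level
        Confidence level of the rank-inversion interval.
    engine
        "css" (fast conditional sum of squares, default) or "statespace"
        (statsmodels exact MLE).
    """

    def __init__(
        self,
        stack: KdRasterStack,
        min_valid_years: int = 10,
        orders: tuple[tuple[int, int], ...] = _DEFAULT_ORDERS,
        ci_level: float = 0.95,
        engine: str = "css",
    ) -> None:
        self.stack = stack
        self.min_valid_years = min_valid_years
        self.orders = orders
        self.ci_level = ci_level
        self.engine = engine

    def fit(self, workers: int = 1) -> "KdTrendResults":
        """Fit every ocean pixel; the result is independent of ``workers``
        and of pixel order.  Per-pixel failures become insufficient_data."""
        grid = self.stack.grid
        pixels = [(r, c) for r in range(grid.n_rows) for c in range(grid.n_cols)]

        def job(rc: tuple[int, int]) -> TrendResult:
            r, c = rc
            return fit_pixel(self.stack.series(r, c), self.stack.years,
                             self.min_valid_years, self.orders,
                             self.ci_level, self.engine)

        if workers > 1:
            from joblib import Parallel, delayed

            results = Parallel(n_jobs=workers, batch_size=256)(
                delayed(job)(rc) for rc in pixels
            )
        else:
            results = [job(rc) for rc in pixels]
        return KdTrendResults.from_pixel_results(self, results)


class KdTrendResults:
    """Fitted per-pixel trend rasters with summary and export helpers."""

    _FIELDS = ("slope", "ci_low", "ci_high", "kd_start", "kd_end")

    def __init__(self, model: KdTrendModel, arrays: dict[str, np.ndarray]) -> None:
        self.model = model
        self.grid: GridSpec = model.stack.grid
        self.years = model.stack.years
        for name, arr in arrays.items():
            setattr(self, name, arr)

    @classmethod
    def from_pixel_results(
        cls, model: KdTrendModel, results: list[TrendResult]
    ) -> "KdTrendResults":
        grid = model.stack.grid
        arrays = {f: np.full(grid.shape, np.nan) for f in cls._FIELDS}
        arrays["classification"] = np.full(grid.shape, CLASS_CODES["insufficient_data"],
                                           dtype=np.int8)
        arrays["n_valid"] = np.zeros(grid.shape, dtype=np.int16)
        arrays["arima_p"] = np.zeros(grid.shape, dtype=np.int8)
        arrays["arima_q"] = np.zeros(grid.shape, dtype=np.int8)
        it = iter(results)
        for r in range(grid.n_rows):
            for c in range(grid.n_cols):
                res = next(it)
                for f in cls._FIELDS:
                    arrays[f][r, c] = getattr(res, f)
                arrays["classification"][r, c] = CLASS_CODES[res.classification]
                arrays["n_valid"][r, c] = res.n_valid
                arrays["arima_p"][r, c] = res.arima_order[0]
                arrays["arima_q"][r, c] = res.arima_order[2]
        return cls(model, arrays)

    def class_mask(self, name: str) -> np.ndarray:
        return self.classification == CLASS_CODES[name]

    def to_dataframe(self) -> pd.DataFrame:
        grid = self.grid
        rows, cols = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
        inv = {v: k for k, v in CLASS_CODES.items()}
        return pd.DataFrame({
            "row": rows.ravel(),
            "col": cols.ravel(),
            "lat": np.repeat(grid.lat_centers, grid.n_cols),
            "lon": np.tile(grid.lon_centers, grid.n_rows),
            "slope": self.slope.ravel(),
            "ci_low": self.ci_low.ravel(),
            "ci_high": self.ci_high.ravel(),
            "classification": [inv[v] for v in self.classification.ravel()],
            "kd_start": self.kd_start.ravel(),
            "kd_end": self.kd_end.ravel(),
            "n_valid": self.n_valid.ravel(),
        })

    def summary(self) -> str:
        n = self.classification.size
        lines = [
            "K_d(490) per-pixel trend results",
            f"  grid: {self.grid.n_rows} x {self.grid.n_cols} pixels, "
            f"years {self.years[0]}-{self.years[-1]}",
            f"  engine: {self.model.engine}, CI level {self.model.ci_level:.2f}",
        ]
        for name in ("increasing", "decreasing", "no_change", "insufficient_data"):
            k = int(self.class_mask(name).sum())
            lines.append(f"  {name:<18s} {k:8d} px  ({100.0 * k / n:5.1f}%)")
        sig = self.class_mask("increasing") | self.class_mask("decreasing")
        if sig.any():
            lines.append(f"  median |slope| of significant pixels: "
                         f"{np.median(np.abs(self.slope[sig])):.3e} m^-1 yr^-1")
        return "\n".join(lines)


def trend_map(stack: KdRasterStack, workers: int = 1, **kwargs) -> KdTrendResults:
    """Functional wrapper: fit the per-pixel trend model over a whole stack."""
    return KdTrendModel(stack, **kwargs).fit(workers=workers)
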