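"""Synthetic data generation: K_d(490) stacks, bathymetry, region masks.

Every downstream stage of the darkening pipeline is testable without any
satellite download by generating rasters with the statistical structure the
analysis assumes: per-pixel linear trends in K_d(490) with AR(1) noise
(annual composites carry serial autocorrelation that the ARIMA stage must
remove), a smooth shelf/abyss bathymetry, and a contiguous partition of the
grid into labelled regions standing in for named sea areas.

All generators are pure functions of (arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import KD_MAX, KD_MIN, BathymetryGrid, GridSpec, KdRasterStack, RegionMask

__all__ = [
    "TrendScenario",
    "SyntheticTruth",
    "ar1_series",
    "generate_kd_stack",
    "generate_bathymetry",
    "generate_region_masks",
]


@dataclass
class TrendScenario:
    """Planted per-pixel trend structure for a synthetic K_d stack.

    ``baseline_kd`` and ``slope`` may be scalars (broadcast) or per-pixel
    arrays.  ``ar1_phi`` is the lag-1 autocorrelation of the annual noise,
    ``noise_sigma`` the innovation standard deviation (m^-1).  The default
    missing fraction emulates independent per-pixel-per-year coverage gaps.
    """

    baseline_kd: float | np.ndarray = 0.1
    slope: float | np.ndarray = 0.0
    ar1_phi: float = 0.5
    noise_sigma: float = 0.005
    years: np.ndarray = field(default_factory=lambda: np.arange(2003, 2023))
    seed: int = 0
    missing_fraction: float = 0.05
    polar_night: bool = False

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in [0, 1) for stationarity")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")
        base = np.asarray(self.baseline_kd, dtype=float)
        if np.any(base <= KD_MIN) or np.any(base > KD_MAX):
            raise ValueError(f"baseline_kd must lie in ({KD_MIN}, {KD_MAX}]")
        span = self.years[-1] - self.years[0]
        expected_end = base + np.asarray(self.slope, dtype=float) * span
        if np.any(expected_end <= KD_MIN) or np.any(expected_end > KD_MAX):
            raise ValueError("slope * span drives expected K_d outside the valid range")


@dataclass
class SyntheticTruth:
    """Planted-truth maps returned alongside a generated stack."""

    slope: np.ndarray
    baseline: np.ndarray
    classification: np.ndarray  # 1 increasing, -1 decreasing, 0 null


def ar1_series(
    n_years: int,
    mean: float,
    slope: float,
    phi: float,
    sigma: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One annual series: mean + slope*t + stationary AR(1) noise.

    The noise is u_t = phi*u_{t-1} + sigma*eps_t with the initial state drawn
    from the stationary marginal N(0, sigma^2/(1-phi^2)), so every time point
    has the same marginal noise variance.
    """
    if n_years < 3:
        raise ValueError("n_years must be at least 3")
    if not 0.0 <= phi < 1.0:
        raise ValueError("phi must lie in [0, 1) for a stationary AR(1)")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n_years, dtype=float)
    trend = mean + slope * t
    if sigma == 0.0:
        return trend
    u = np.empty(n_years)
    u[0] = rng.normal(0.0, sigma / np.sqrt(1.0 - phi**2))
    eps = rng.normal(0.0, sigma, n_years - 1)
    for i in range(1, n_years):
        u[i] = phi * u[i - 1] + eps[i - 1]
    return trend + u


def _ar1_field(shape: tuple[int, ...], n_years: int, phi: float, sigma: float,
               rng: np.random.Generator) -> np.ndarray:
    """Vectorized AR(1) noise, one independent series per pixel; (year, ...)."""
    out = np.zeros((n_years,) + shape)
    if sigma == 0.0:
        return out
    out[0] = rng.normal(0.0, sigma / np.sqrt(1.0 - phi**2), shape)
    for i in range(1, n_years):
        out[i] = phi * out[i - 1] + rng.normal(0.0, sigma, shape)
    return out


def generate_kd_stack(
    grid: GridSpec, scenario: TrendScenario
) -> tuple[KdRasterStack, SyntheticTruth]:
    """Generate an annual K_d(490) stack with planted linear trends.

    Returns the stack together with the planted-truth maps (slope field and
    its sign classification) for parameter-recovery tests.  Values are
    clamped to the K_d validity range; a ``missing_fraction`` of cells is
    dropped out (NaN) independently per pixel-year, or as whole winters when
    ``polar_night`` is set.
    """
    base = np.broadcast_to(np.asarray(scenario.baseline_kd, dtype=float), grid.shape).copy()
    slope = np.broadcast_to(np.asarray(scenario.slope, dtype=float), grid.shape).copy()
    if base.shape != grid.shape or slope.shape != grid.shape:
        raise ValueError("baseline/slope fields do not conform to the grid shape")
    n_years = len(scenario.years)
    rng = np.random.default_rng(scenario.seed)
    t = np.arange(n_years, dtype=float)[:, None, None]
    values = base[None] + slope[None] * t
    values = values + _ar1_field(grid.shape, n_years, scenario.ar1_phi,
                                 scenario.noise_sigma, rng)
    np.clip(values, KD_MIN + 1e-9, KD_MAX, out=values)

    missing = np.zeros(values.shape, dtype=bool)
    if scenario.missing_fraction > 0:
        if scenario.polar_night:
            # whole-year dropout for high-latitude rows, mimicking winters
            # with no retrievable ocean-colour data
            lat = np.abs(grid.lat_centers)
            polar_rows = lat > 66.5
            year_drop = rng.random((n_years,)) < scenario.missing_fraction * 4
            missing[np.ix_(year_drop, polar_rows, np.arange(grid.n_cols))] = True
        else:
            missing = rng.random(values.shape) < scenario.missing_fraction
    values[missing] = np.nan

    classification = np.sign(slope).astype(int)
    truth = SyntheticTruth(slope=slope, baseline=base, classification=classification)
    stack = KdRasterStack(grid=grid, years=scenario.years, values=values, missing=missing)
    return stack, truth


def generate_bathymetry(
    grid: GridSpec, shelf_depth: float = 50.0, abyss_depth: float = 4000.0,
    seed: int = 0, shelf_width_frac: float = 0.12,
) -> BathymetryGrid:
    """Smooth positive-down depth field with a coastal shelf band.

    Pixels near the grid boundary sit on a shallow shelf near ``shelf_depth``;
    the interior deepens smoothly toward ``abyss_depth``, with mild correlated
    roughness superposed.  All ocean depths stay within [~shelf, abyss].
    """
    if not 0 < shelf_depth < abyss_depth:
        raise ValueError("require 0 < shelf_depth < abyss_depth")
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
    # normalized distance from the nearest grid edge, in [0, 0.5]
    d = np.minimum.reduce([
        rows / max(grid.n_rows - 1, 1),
        1 - rows / max(grid.n_rows - 1, 1),
        cols / max(grid.n_cols - 1, 1),
        1 - cols / max(grid.n_cols - 1, 1),
    ])
    ramp = np.clip(d / shelf_width_frac, 0.0, 1.0)
    profile = shelf_depth + (abyss_depth - shelf_depth) * np.sin(ramp * np.pi / 2) ** 2
    rough = ndimage.gaussian_filter(rng.normal(0.0, 1.0, grid.shape),
                                    sigma=max(min(grid.shape) / 16, 1.0))
    rough /= max(np.abs(rough).max(), 1e-12)
    depth = profile * (1.0 + 0.05 * rough)
    depth = np.clip(depth, shelf_depth * 0.9, abyss_depth)
    return BathymetryGrid(grid=grid, depth=depth)


def generate_region_masks(grid: GridSpec, n_regions: int, seed: int = 0) -> RegionMask:
    """Partition the grid into ``n_regions`` contiguous labelled regions.

    Regions are Voronoi cells of random seed points (convex in index space,
    hence contiguous); every pixel receives exactly one label.
    """
    n_pixels = grid.n_rows * grid.n_cols
    if not 1 <= n_regions <= n_pixels:
        raise ValueError("n_regions must lie in [1, n_pixels]")
    rng = np.random.default_rng(seed)
    rows, cols = np.mgrid[0 : grid.n_rows, 0 : grid.n_cols]
    # sample distinct seed pixels
    flat = rng.choice(n_pixels, size=n_regions, replace=False)
    sr, sc = np.unravel_index(flat, grid.shape)
    d2 = (rows[..., None] - sr) ** 2 + (cols[..., None] - sc) ** 2
    region_id = np.argmin(d2, axis=-1).astype(int)
    names = {i: f"Sea {chr(65 + i % 26)}{'' if i < 26 else i // 26}" for i in range(n_regions)}
    return RegionMask(grid=grid, region_id=region_id, names=names)
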