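"""Area-based summaries of trend and photic-zone-change rasters.

Pixel areas come in two modes: ``spherical`` (exact cell area on the
sphere, R^2 * dlon * (sin(lat2) - sin(lat1))) and ``mercator_grid`` (the
ground footprint (s * cos(lat))^2 of a point spaced s metres apart in World
Mercator projected coordinates, for fidelity with analyses that count
Mercator grid points).  The Mercator projection is not equal-area, so the
two modes disagree away from the equator by design; the spherical mode is
the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GridSpec, RegionMask
from .photic import PhoticZoneField

__all__ = [
    "EARTH_RADIUS_KM",
    "pixel_area",
    "cell_area_field",
    "region_trend_summary",
    "threshold_areas",
    "delta_histogram",
]

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius

#: Reduction thresholds reported by the pipeline: metres and percent.
DEPTH_THRESHOLDS_M = (10.0, 50.0, 100.0)
PCT_THRESHOLDS = (10.0, 50.0)


def pixel_area(latitude: float, grid: GridSpec, mode: str = "spherical",
               spacing_m: float = 9000.0) -> float:
    """Area (km^2) of one grid cell / grid point at the given latitude.

    spherical: exact cell area between the cell's latitude edges;
    mercator_grid: (s * cos(lat))^2 for point spacing s in projected metres.
    A cell touching the pole degenerates gracefully toward zero.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude must lie in [-90, 90]")
    if mode == "mercator_grid":
        return float((spacing_m / 1000.0 * np.cos(np.radians(latitude))) ** 2)
    if mode != "spherical":
        raise ValueError("mode must be 'spherical' or 'mercator_grid'")
    half = grid.cell_size / 2.0
    lat1 = np.radians(max(latitude - half, -90.0))
    lat2 = np.radians(min(latitude + half, 90.0))
    dlon = np.radians(grid.cell_size)
    return float(EARTH_RADIUS_KM**2 * dlon * (np.sin(lat2) - np.sin(lat1)))


def cell_area_field(grid: GridSpec, mode: str = "spherical",
                    spacing_m: float = 9000.0) -> np.ndarray:
    """Per-pixel area raster (km^2)."""
    col = np.array([pixel_area(lat, grid, mode=mode, spacing_m=spacing_m)
                    for lat in grid.lat_centers])
    return np.repeat(col[:, None], grid.n_cols, axis=1)


@dataclass
class RegionSummary:
    """Ranked per-region darkening table plus global threshold/histogram
    areas; produced by the aggregation stage."""

    table: pd.DataFrame              # one row per region, ranked
    total_area: float                # km^2, assessed ocean

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"RegionSummary({len(self.table)} regions, {self.total_area:.3e} km^2)"


def region_trend_summary(
    classification: np.ndarray, mask: RegionMask, mode: str = "spherical",
    spacing_m: float = 9000.0,
) -> RegionSummary:
    """Per-region areas by trend class, ranked by percent-of-region
    increasing.

    ``classification`` uses the raster codes (1 increasing, -1 decreasing,
    0 no change, -9 insufficient data).  Insufficient pixels are excluded
    from every percentage denominator and reported separately.
    """
    grid = mask.grid
    classification = np.asarray(classification)
    if classification.shape != grid.shape:
        raise ValueError("classification raster must match the region grid")
    areas = cell_area_field(grid, mode=mode, spacing_m=spacing_m)
    rows = []
    for rid in mask.ids:
        sel = mask.region_id == rid
        a_inc = float(areas[sel & (classification == 1)].sum())
        a_dec = float(areas[sel & (classification == -1)].sum())
        a_no = float(areas[sel & (classification == 0)].sum())
        a_bad = float(areas[sel & (classification == -9)].sum())
        assessed = a_inc + a_dec + a_no
        rows.append({
            "region_id": int(rid),
            "region_name": mask.names[int(rid)],
            "total_area_km2": assessed + a_bad,
            "assessed_area_km2": assessed,
            "area_increasing_km2": a_inc,
            "area_decreasing_km2": a_dec,
            "area_no_change_km2": a_no,
            "area_insufficient_km2": a_bad,
            "pct_increasing": 100.0 * a_inc / assessed if assessed > 0 else np.nan,
            "pct_decreasing": 100.0 * a_dec / assessed if assessed > 0 else np.nan,
        })
    table = pd.DataFrame(rows).sort_values(
        "pct_increasing", ascending=False, kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return RegionSummary(table=table, total_area=float(areas[mask.region_id >= 0].sum()))


def threshold_areas(
    delta: PhoticZoneField | np.ndarray,
    mode: str = "spherical",
    spacing_m: float = 9000.0,
    luminary: str = "sun",
    grid: GridSpec | None = None,
    pct_change: np.ndarray | None = None,
) -> pd.DataFrame:
    """Areas with photic-depth reductions exceeding fixed depth and percent
    thresholds (strict '>', on the reduction magnitude -delta_z).

    Returns a table with one row per threshold: area (km^2) and percent of
    the assessed ocean area.
    """
    if isinstance(delta, PhoticZoneField):
        grid = delta.grid
        dz = delta.delta_z[luminary]
        pct = delta.pct_change[luminary]
    else:
        if grid is None:
            raise ValueError("grid required when passing a bare delta array")
        dz = np.asarray(delta, dtype=float)
        pct = pct_change
    areas = cell_area_field(grid, mode=mode, spacing_m=spacing_m)
    ocean = np.isfinite(dz)
    total = float(areas[ocean].sum())
    reduction = -dz  # positive where the photic zone shoaled
    rows = []
    for thr in DEPTH_THRESHOLDS_M:
        a = float(areas[ocean & (reduction > thr)].sum())
        rows.append({"threshold": f">{thr:g} m", "kind": "depth",
                     "area_km2": a, "pct_of_ocean": 100.0 * a / total if total else np.nan})
    if pct is not None:
        red_pct = -np.asarray(pct, dtype=float)
        for thr in PCT_THRESHOLDS:
            a = float(areas[ocean & (red_pct > thr)].sum())
            rows.append({"threshold": f">{thr:g} %", "kind": "percent",
                         "area_km2": a, "pct_of_ocean": 100.0 * a / total if total else np.nan})
    out = pd.DataFrame(rows)
    out.attrs["total_area_km2"] = total
    out.attrs["luminary"] = luminary
    return out


def delta_histogram(
    delta: PhoticZoneField | np.ndarray,
    bin_width: float = 10.0,
    mode: str = "spherical",
    spacing_m: float = 9000.0,
    luminary: str = "sun",
    grid: GridSpec | None = None,
) -> pd.DataFrame:
    """Area per ``bin_width``-metre increment of photic-depth change.

    Reductions fill left-open bins (0, 10], (10, 20], ... of the reduction
    magnitude; increases are binned the same way with sign 'increase'.
    Bin areas sum exactly to the area with nonzero delta.
    """
    if isinstance(delta, PhoticZoneField):
        grid = delta.grid
        dz = delta.delta_z[luminary]
    else:
        if grid is None:
            raise ValueError("grid required when passing a bare delta array")
        dz = np.asarray(delta, dtype=float)
    areas = cell_area_field(grid, mode=mode, spacing_m=spacing_m)
    ocean = np.isfinite(dz)
    rows = []
    for sign, vals in (("reduction", -dz), ("increase", dz)):
        sel = ocean & (vals > 0)
        if not sel.any():
            continue
        mags = vals[sel]
        cell_areas = areas[sel]
        n_bins = int(np.ceil(mags.max() / bin_width))
        edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)
        # left-open bins (lo, hi]: searchsorted with side='left' on the mag
        idx = np.searchsorted(edges, mags, side="left") - 1
        idx = np.clip(idx, 0, n_bins - 1)
        for b in range(n_bins):
            a = float(cell_areas[idx == b].sum())
            if a > 0:
                rows.append({"bin_low_m": edges[b], "bin_high_m": edges[b + 1],
                             "direction": sign, "area_km2": a,
                             "luminary": luminary})
    return pd.DataFrame(rows, columns=["bin_low_m", "bin_high_m", "direction",
                                       "area_km2", "luminary"])
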