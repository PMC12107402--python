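"""Minimal GeoTIFF I/O and Mercator point-grid resampling.

Rasters are written as float32 multi-page TIFFs with the GeoTIFF
georeferencing tags (pixel scale, tiepoint, geographic WGS84 key directory)
and the GDAL nodata convention (-999).  Row 0 is the northernmost row and
values are cell-center registered on a regular lat/lon grid.

The point-grid resampler reproduces the fixed-metre-spacing sampling
workflow: points laid out at constant spacing in World Mercator projected
coordinates, inverse-projected to geographic coordinates, and sampled
nearest-neighbour so each year sees the identical point set.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .grids import GridSpec, KdRasterStack

__all__ = [
    "NODATA",
    "write_raster",
    "read_raster",
    "write_stack",
    "read_raster_stack",
    "mercator_point_grid",
    "sample_at_points",
    "resample_to_point_grid",
]

NODATA = -999.0
_WGS84_A = 6378137.0  # semi-major axis, m

# GeoTIFF tag ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GEO_KEY_DIRECTORY = 34735
_GDAL_NODATA = 42113


def _geo_tags(grid: GridSpec) -> list[tuple]:
    keys = (1, 1, 0, 3,          # version, revision, minor, count
            1024, 0, 1, 2,       # model type: geographic
            1025, 0, 1, 1,       # raster type: pixel-is-area
            2048, 0, 1, 4326)    # geographic CRS: WGS84
    return [
        (_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0), True),
        (_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.lon_min, grid.lat_max, 0.0), True),
        (_GEO_KEY_DIRECTORY, "H", len(keys), keys, True),
        (_GDAL_NODATA, "s", 0, str(NODATA), True),
    ]


def write_raster(path: str | Path, grid: GridSpec, bands: np.ndarray,
                 band_names: list[str] | None = None) -> Path:
    """Write one or more bands (rows x cols, or bands x rows x cols) as a
    georeferenced multi-page float32 TIFF; NaN becomes the nodata value."""
    path = Path(path)
    bands = np.asarray(bands, dtype=np.float32)
    if bands.ndim == 2:
        bands = bands[None]
    if bands.shape[-2:] != grid.shape:
        raise ValueError("band shape does not match grid")
    data = np.where(np.isfinite(bands), bands, np.float32(NODATA))
    tags = _geo_tags(grid)
    with tifffile.TiffWriter(path) as tw:
        for i, page in enumerate(data):
            desc = band_names[i] if band_names else None
            tw.write(page, extratags=tags, description=desc)
    return path


def read_raster(path: str | Path) -> tuple[GridSpec, np.ndarray, list[str | None]]:
    """Read a georeferenced TIFF back to (grid, bands, band descriptions);
    nodata cells become NaN."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pages = tf.pages
        first = pages[0]
        scale = first.tags[_MODEL_PIXEL_SCALE].value
        tie = first.tags[_MODEL_TIEPOINT].value
        nodata = float(first.tags[_GDAL_NODATA].value) if _GDAL_NODATA in first.tags else NODATA
        arrs, names = [], []
        for p in pages:
            arrs.append(p.asarray().astype(float))
            names.append(p.tags.get("ImageDescription").value
                         if "ImageDescription" in p.tags else None)
    bands = np.stack(arrs)
    n_rows, n_cols = bands.shape[-2:]
    cell = float(scale[0])
    lon_min, lat_max = float(tie[3]), float(tie[4])
    grid = GridSpec(n_rows, n_cols,
                    lat_min=lat_max - n_rows * cell, lat_max=lat_max,
                    lon_min=lon_min, lon_max=lon_min + n_cols * cell,
                    cell_size=cell)
    bands[bands == nodata] = np.nan
    return grid, bands, names


def write_stack(path: str | Path, stack: KdRasterStack) -> Path:
    """Write an annual stack as a multi-page GeoTIFF, one page per year."""
    vals = stack.values.copy()
    vals[stack.missing] = np.nan
    return write_raster(path, stack.grid, vals,
                        band_names=[str(y) for y in stack.years])


def read_raster_stack(
    paths: str | Path | list[str | Path], years: list[int] | None = None
) -> KdRasterStack:
    """Read a K_d stack from one multi-page file or one file per year.

    Grids must agree across files; the offending file is named otherwise.
    """
    if isinstance(paths, (str, Path)):
        grid, bands, names = read_raster(paths)
        if years is None:
            try:
                years = [int(n) for n in names]
            except (TypeError, ValueError):
                raise ValueError("years not given and not recoverable from band names")
    else:
        grid = None
        bands_list = []
        for p in paths:
            g, b, _ = read_raster(p)
            if grid is None:
                grid = g
            elif g != grid:
                raise ValueError(f"inconsistent grid in {p}")
            if b.shape[0] != 1:
                raise ValueError(f"expected single-band file, got {b.shape[0]} in {p}")
            bands_list.append(b[0])
        bands = np.stack(bands_list)
        if years is None:
            raise ValueError("years must be given with file-per-year input")
    return KdRasterStack(grid=grid, years=np.asarray(years), values=bands)


# --- World Mercator point grid -------------------------------------------

def _mercator_forward(lat: float | np.ndarray, lon: float | np.ndarray):
    lat = np.clip(lat, -89.99, 89.99)
    x = _WGS84_A * np.radians(lon)
    y = _WGS84_A * np.log(np.tan(np.pi / 4 + np.radians(lat) / 2))
    return x, y


def _mercator_inverse(x: np.ndarray, y: np.ndarray):
    lon = np.degrees(x / _WGS84_A)
    lat = np.degrees(2 * np.arctan(np.exp(y / _WGS84_A)) - np.pi / 2)
    return lat, lon


def mercator_point_grid(grid: GridSpec, spacing_m: float = 9000.0
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Latitudes/longitudes of points spaced ``spacing_m`` apart in World
    Mercator projected space, covering the grid's bounds."""
    x0, y0 = _mercator_forward(grid.lat_min, grid.lon_min)
    x1, y1 = _mercator_forward(grid.lat_max, grid.lon_max)
    xs = np.arange(x0 + spacing_m / 2, x1, spacing_m)
    ys = np.arange(y0 + spacing_m / 2, y1, spacing_m)
    xx, yy = np.meshgrid(xs, ys)
    lat, lon = _mercator_inverse(xx.ravel(), yy.ravel())
    return lat, lon


def sample_at_points(grid: GridSpec, band: np.ndarray, lats: np.ndarray,
                     lons: np.ndarray) -> np.ndarray:
    """Nearest-neighbour sample of a single band at geographic points;
    points outside the raster return NaN."""
    rows = np.floor((grid.lat_max - np.asarray(lats)) / grid.cell_size).astype(int)
    cols = np.floor((np.asarray(lons) - grid.lon_min) / grid.cell_size).astype(int)
    out = np.full(len(rows), np.nan)
    ok = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
    out[ok] = band[rows[ok], cols[ok]]
    return out


def resample_to_point_grid(stack: KdRasterStack, spacing_m: float = 9000.0):
    """Sample every year of a stack at a fixed Mercator point grid.

    Returns (lats, lons, samples) with samples shaped (n_years, n_points);
    the point set is identical across years by construction.
    """
    lats, lons = mercator_point_grid(stack.grid, spacing_m=spacing_m)
    vals = stack.values.copy()
    vals[stack.missing] = np.nan
    samples = np.stack([sample_at_points(stack.grid, band, lats, lons)
                        for band in vals])
    return lats, lons, samples
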