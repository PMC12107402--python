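"""Core gridded containers shared by every pipeline stage.

All rasters follow the GeoTIFF convention: row 0 is the northernmost row,
coordinates are geographic WGS84 degrees, and cell values are registered to
cell centers.  Depths are metres, positive down; K_d(490) is m^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Valid range of the K_d(490) product, m^-1 (open at the low end).
KD_MIN = 0.01
KD_MAX = 6.4


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid: shape, bounds and cell size in degrees."""

    n_rows: int
    n_cols: int
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    cell_size: float

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid shape must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ValueError("latitude bounds must satisfy -90 <= min < max <= 90")
        if not (-180.0 <= self.lon_min < self.lon_max <= 180.0):
            raise ValueError("longitude bounds must satisfy -180 <= min < max <= 180")
        if not np.isclose(self.n_rows * self.cell_size, self.lat_max - self.lat_min,
                          rtol=1e-6, atol=1e-9):
            raise ValueError("n_rows * cell_size must span the latitude range")
        if not np.isclose(self.n_cols * self.cell_size, self.lon_max - self.lon_min,
                          rtol=1e-6, atol=1e-9):
            raise ValueError("n_cols * cell_size must span the longitude range")

    @classmethod
    def global_grid(cls, cell_size: float) -> "GridSpec":
        n_rows = int(round(180.0 / cell_size))
        n_cols = int(round(360.0 / cell_size))
        return cls(n_rows, n_cols, -90.0, 90.0, -180.0, 180.0, cell_size)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, row 0 northernmost (descending)."""
        edges = np.linspace(self.lat_max, self.lat_min, self.n_rows + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def lon_centers(self) -> np.ndarray:
        edges = np.linspace(self.lon_min, self.lon_max, self.n_cols + 1)
        return 0.5 * (edges[:-1] + edges[1:])

    @property
    def lat_edges(self) -> np.ndarray:
        """Latitude cell edges, descending from lat_max to lat_min."""
        return np.linspace(self.lat_max, self.lat_min, self.n_rows + 1)


def _check_grid_array(grid: GridSpec, arr: np.ndarray, name: str) -> None:
    if arr.shape[-2:] != grid.shape:
        raise ValueError(f"{name} shape {arr.shape} does not match grid {grid.shape}")


@dataclass
class KdRasterStack:
    """Annual K_d(490) rasters on a common grid.

    ``values`` is (year, row, col); missing cells are flagged in ``missing``
    (and hold NaN in ``values``).
    """

    grid: GridSpec
    years: np.ndarray
    values: np.ndarray
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != len(self.years):
            raise ValueError("values must be (n_years, n_rows, n_cols)")
        _check_grid_array(self.grid, self.values, "values")
        if len(self.years) >= 2 and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be strictly increasing with unit step")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise ValueError("missing mask shape must match values")
        valid = self.values[~self.missing]
        if valid.size and (np.nanmin(valid) <= 0 or np.nanmax(valid) > KD_MAX):
            raise ValueError(f"non-missing K_d values must lie in (0, {KD_MAX}]")

    @property
    def n_years(self) -> int:
        return len(self.years)

    def series(self, row: int, col: int) -> np.ndarray:
        """Annual series at a pixel, NaN where missing."""
        s = self.values[:, row, col].copy()
        s[self.missing[:, row, col]] = np.nan
        return s


@dataclass
class BathymetryGrid:
    """Sea-floor depth (m, positive down) on a grid."""

    grid: GridSpec
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        _check_grid_array(self.grid, self.depth, "depth")
        ocean = np.isfinite(self.depth)
        if ocean.any() and np.nanmin(self.depth[ocean]) <= 0:
            raise ValueError("ocean depths must be positive (positive-down)")


@dataclass
class RegionMask:
    """Partition of ocean pixels into labelled contiguous regions.

    ``region_id`` is int; -1 marks non-ocean/unassigned pixels.
    """

    grid: GridSpec
    region_id: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.region_id = np.asarray(self.region_id, dtype=int)
        _check_grid_array(self.grid, self.region_id, "region_id")
        ids = np.unique(self.region_id[self.region_id >= 0])
        for i in ids:
            if int(i) not in self.names:
                self.names[int(i)] = f"region_{int(i)}"

    @property
    def ids(self) -> np.ndarray:
        return np.unique(self.region_id[self.region_id >= 0])
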