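"""Photic-zone depths from Beer's law and their 2003 -> 2022 change.

With a vertically constant diffuse attenuation coefficient K_d(490), the
depth at which 490 nm irradiance falls to a photosensitivity threshold
I_sens is

    Z_photic = -(1 / K_d) * ln(I_sens / I_0),

where I_0 is the band irradiance just above the sea surface (sunlight or
full moonlight).  The default threshold, 0.027 uW m^-2, is the minimum
490 nm irradiance that elicits diel vertical migration in Calanus copepods;
the classical alternative defines the photic zone at 1% of surface
irradiance, Z = ln(100) / K_d, identical for sun and moon.  Z is floored at
zero where the surface irradiance itself is at or below the threshold
(polar night) and clipped to the bathymetric depth.

The change field evaluates Z for the start-year and end-year K_d in every
month of a typical year, clips each to bathymetry, differences, and
averages the twelve monthly differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import BathymetryGrid, GridSpec
from .irradiance import SurfaceIrradianceField

__all__ = [
    "PhoticConfig",
    "PhoticZoneField",
    "zphotic_threshold",
    "zphotic_one_percent",
    "clip_to_bathymetry",
    "delta_field",
]

#: Calanus DVM photosensitivity threshold: 0.027 uW m^-2 in W m^-2.
I_SENS_CALANUS = 2.7e-8


@dataclass
class PhoticConfig:
    """Photic-zone definition: species threshold or 1%-of-surface."""

    i_sens: float = I_SENS_CALANUS
    definition: str = "threshold"  # or "one_percent"

    def __post_init__(self) -> None:
        if self.i_sens <= 0:
            raise ValueError("i_sens must be positive")
        if self.definition not in ("threshold", "one_percent"):
            raise ValueError("definition must be 'threshold' or 'one_percent'")

    @classmethod
    def from_microwatts(cls, i_sens_uw_m2: float, definition: str = "threshold") -> "PhoticConfig":
        """Build from a threshold in uW m^-2 (the unit conversion happens
        once, here; everything downstream is W m^-2)."""
        return cls(i_sens=i_sens_uw_m2 * 1e-6, definition=definition)


def zphotic_threshold(kd, i0_band, cfg: PhoticConfig | None = None):
    """Beer's-law photic depth (m) for K_d (m^-1) and surface band
    irradiance (W m^-2); floored at 0 when I_0 <= I_sens (incl. I_0 = 0)."""
    cfg = cfg or PhoticConfig()
    kd = np.asarray(kd, dtype=float)
    i0 = np.asarray(i0_band, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("kd must be positive")
    if np.any(i0 < 0):
        raise ValueError("surface irradiance must be nonnegative")
    with np.errstate(divide="ignore"):
        z = np.where(i0 > cfg.i_sens, np.log(i0 / cfg.i_sens) / kd, 0.0)
    return float(z) if z.ndim == 0 else z


def zphotic_one_percent(kd):
    """Photic depth under the classical 1%-of-surface definition:
    Z = ln(100) / K_d, independent of the surface irradiance."""
    kd = np.asarray(kd, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("kd must be positive")
    z = np.log(100.0) / kd
    return float(z) if z.ndim == 0 else z


def clip_to_bathymetry(z, depth):
    """Clip photic depth to the sea floor; a tie counts as clipped."""
    z = np.asarray(z, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(depth <= 0):
        raise ValueError("bathymetric depth must be positive")
    if np.any(z < 0):
        raise ValueError("photic depth must be nonnegative")
    clipped = z >= depth
    zc = np.minimum(z, depth)
    if zc.ndim == 0:
        return float(zc), bool(clipped)
    return zc, clipped


@dataclass
class PhoticZoneField:
    """Gridded photic-zone change between a start and end year.

    Monthly depths are (month, row, col) per luminary; ``delta_z`` is the
    annual mean of the twelve monthly (clipped) differences and
    ``pct_change`` its percentage relative to the start-year depth.
    """

    grid: GridSpec
    luminaries: tuple[str, ...]
    z_start: dict[str, np.ndarray]      # luminary -> (12, rows, cols)
    z_end: dict[str, np.ndarray]
    delta_z: dict[str, np.ndarray]      # luminary -> (rows, cols)
    pct_change: dict[str, np.ndarray]
    clipped_fraction: dict[str, np.ndarray]
    pct_undefined: dict[str, np.ndarray] = field(default_factory=dict)

    def annual_mean_z(self, luminary: str, which: str = "start") -> np.ndarray:
        arr = self.z_start if which == "start" else self.z_end
        return arr[luminary].mean(axis=0)


def delta_field(
    kd_start_map: np.ndarray,
    kd_end_map: np.ndarray,
    irradiance: SurfaceIrradianceField,
    bathy: BathymetryGrid,
    cfg: PhoticConfig | None = None,
    luminaries: tuple[str, ...] = ("sun", "moon"),
) -> PhoticZoneField:
    """Photic-zone change field from endpoint K_d maps.

    For each pixel, month and luminary the start- and end-year depths are
    computed with that month's surface band irradiance at the pixel's
    latitude, clipped to bathymetry, differenced, then averaged over the 12
    months.  pct_change = 100 * delta / z_start_annual, defined as 0 (and
    flagged) where the start depth is zero.
    """
    cfg = cfg or PhoticConfig()
    grid = bathy.grid
    kd_start_map = np.asarray(kd_start_map, dtype=float)
    kd_end_map = np.asarray(kd_end_map, dtype=float)
    if kd_start_map.shape != grid.shape or kd_end_map.shape != grid.shape:
        raise ValueError("K_d maps must match the bathymetry grid")

    sun_rows, moon_rows = irradiance.interp_rows(grid.lat_centers)  # (rows, 12)
    bands = {"sun": sun_rows, "moon": moon_rows}
    ocean = np.isfinite(kd_start_map) & np.isfinite(kd_end_map) & (kd_start_map > 0)

    z_start: dict[str, np.ndarray] = {}
    z_end: dict[str, np.ndarray] = {}
    delta: dict[str, np.ndarray] = {}
    pct: dict[str, np.ndarray] = {}
    clip_frac: dict[str, np.ndarray] = {}
    pct_undef: dict[str, np.ndarray] = {}

    depth = bathy.depth
    for lum in luminaries:
        zs = np.zeros((12,) + grid.shape)
        ze = np.zeros((12,) + grid.shape)
        nclip = np.zeros(grid.shape)
        for m in range(12):
            i0 = np.broadcast_to(bands[lum][:, m][:, None], grid.shape)
            if cfg.definition == "one_percent":
                z0 = np.where(ocean, zphotic_one_percent(np.where(ocean, kd_start_map, 1.0)), 0.0)
                z1 = np.where(ocean, zphotic_one_percent(np.where(ocean, kd_end_map, 1.0)), 0.0)
            else:
                z0 = np.where(ocean, zphotic_threshold(
                    np.where(ocean, kd_start_map, 1.0), i0, cfg), 0.0)
                z1 = np.where(ocean, zphotic_threshold(
                    np.where(ocean, kd_end_map, 1.0), i0, cfg), 0.0)
            c0 = z0 >= depth
            c1 = z1 >= depth
            zs[m] = np.minimum(z0, depth)
            ze[m] = np.minimum(z1, depth)
            nclip += (c0 | c1) / 12.0
        d = (ze - zs).mean(axis=0)
        zs_annual = zs.mean(axis=0)
        undef = zs_annual <= 0
        p = np.where(undef, 0.0, 100.0 * d / np.where(undef, 1.0, zs_annual))
        d = np.where(ocean, d, np.nan)
        p = np.where(ocean, p, np.nan)
        z_start[lum], z_end[lum] = zs, ze
        delta[lum], pct[lum] = d, p
        clip_frac[lum] = np.where(ocean, nclip, np.nan)
        pct_undef[lum] = undef & ocean

    return PhoticZoneField(grid=grid, luminaries=tuple(luminaries),
                           z_start=z_start, z_end=z_end, delta_z=delta,
                           pct_change=pct, clipped_fraction=clip_frac,
                           pct_undefined=pct_undef)
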