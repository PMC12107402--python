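"""Above-surface solar and full-moon spectral irradiance at 490 nm.

The chain is: extraterrestrial solar spectrum corrected for orbital
eccentricity -> clear-sky marine atmosphere (Rayleigh, aerosol, ozone,
oxygen and water-vapour transmittances with single-scattering Rayleigh and
aerosol diffuse terms, after Gregg & Carder) -> band integration over
485-495 nm.  Moonlight follows the same path after reflecting the TOA solar
spectrum off a Lambertian lunar disk: E_moon(lambda) =
E_sun(lambda) * A(lambda) * f(alpha) * theta_s^2, with A the spectral
albedo, f the phase curve normalized to 1 at opposition, and theta_s the
lunar semi-diameter in radians.

The monthly surface field evaluates the sun on the 15th of each month at
solar noon and the moon at its culmination on the month's full-moon date,
per latitude.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from . import ephemeris

__all__ = [
    "SpectralIrradiance",
    "SolarConfig",
    "AtmosphereParams",
    "LunarConfig",
    "LunarGeometry",
    "SurfaceIrradianceField",
    "toa_solar",
    "solar_noon_zenith",
    "gregg_carder_surface",
    "lumme_bowell_phase",
    "lunar_toa",
    "lunar_geometry",
    "monthly_culmination",
    "band_integrate",
    "surface_irradiance_field",
]


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("oceandark.data").joinpath(name).open() as f:
        return pd.read_csv(f, comment="#", header=None)


@lru_cache(maxsize=1)
def _solar_spectrum() -> tuple[np.ndarray, np.ndarray]:
    df = _load_table("solar_spectrum.csv")
    return df[0].to_numpy(float), df[1].to_numpy(float)


@lru_cache(maxsize=1)
def _lunar_albedo() -> tuple[np.ndarray, np.ndarray]:
    df = _load_table("lunar_albedo.csv")
    return df[0].to_numpy(float), df[1].to_numpy(float)


@lru_cache(maxsize=1)
def _gas_absorption() -> pd.DataFrame:
    df = _load_table("gas_absorption.csv")
    df.columns = ["wavelength", "a_ozone", "a_water", "a_oxygen"]
    return df


@dataclass
class SpectralIrradiance:
    """Spectral irradiance on a 1 nm grid, split into direct and diffuse."""

    wavelengths: np.ndarray
    direct: np.ndarray
    diffuse: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.direct = np.asarray(self.direct, dtype=float)
        self.diffuse = np.asarray(self.diffuse, dtype=float)
        if not (len(self.wavelengths) == len(self.direct) == len(self.diffuse)):
            raise ValueError("wavelengths, direct, diffuse must have equal length")
        if np.any(self.direct < 0) or np.any(self.diffuse < 0):
            raise ValueError("irradiance components must be nonnegative")

    @property
    def global_(self) -> np.ndarray:
        """Global irradiance: direct + diffuse, elementwise."""
        return self.direct + self.diffuse


@dataclass
class SolarConfig:
    """Orbital eccentricity and the packaged extraterrestrial spectrum."""

    eccentricity: float = 0.0167

    def __post_init__(self) -> None:
        if not 0.0 <= self.eccentricity < 0.1:
            raise ValueError("eccentricity must lie in [0, 0.1)")
        self.wavelengths, self.h0 = _solar_spectrum()
        if np.any(self.h0[(self.wavelengths >= 400) & (self.wavelengths <= 700)] <= 0):
            raise ValueError("solar spectrum must be positive over 400-700 nm")


@dataclass
class AtmosphereParams:
    """Clear-sky marine atmosphere settings (all overridable via config)."""

    pressure_hpa: float = 1013.25
    water_vapor_cm: float = 2.5
    ozone_du: float = 350.0
    rel_humidity_pct: float = 80.0
    wind_speed_ms: float = 5.0
    visibility_km: float = 23.0
    air_mass_type: str = "marine"
    angstrom_exponent: float = 0.5     # marine aerosols are spectrally flat
    single_scatter_albedo: float = 0.95
    asymmetry: float = 0.65            # aerosol scattering asymmetry <cos>
    aerosol_scale_height_km: float = 1.0

    def __post_init__(self) -> None:
        if min(self.pressure_hpa, self.water_vapor_cm, self.ozone_du,
               self.wind_speed_ms, self.visibility_km) <= 0:
            raise ValueError("atmosphere parameters must be positive")
        if not 0.0 <= self.rel_humidity_pct <= 100.0:
            raise ValueError("relative humidity must lie in [0, 100]")

    @property
    def aerosol_tau_550(self) -> float:
        """Aerosol optical thickness at 550 nm from horizontal visibility."""
        return max((3.912 / self.visibility_km - 0.01159)
                   * self.aerosol_scale_height_km, 0.0)


@dataclass
class LunarConfig:
    """Lunar albedo table, mean semi-diameter and phase-curve parameters."""

    semi_diameter_deg: float = 0.26
    slope_parameter: float = 0.08  # H,G phase-curve G; small = steep surge

    def __post_init__(self) -> None:
        if self.semi_diameter_deg <= 0:
            raise ValueError("semi-diameter must be positive")
        self.albedo_wavelengths, self.albedo = _lunar_albedo()
        if np.any(self.albedo <= 0) or np.any(self.albedo >= 1):
            raise ValueError("albedo must lie in (0, 1)")

    def albedo_at(self, wavelengths: np.ndarray) -> np.ndarray:
        return np.interp(wavelengths, self.albedo_wavelengths, self.albedo)


@dataclass
class LunarGeometry:
    """Observer-dependent lunar viewing geometry at one instant."""

    zenith: float
    phase_angle: float
    instant: dt.datetime

    def __post_init__(self) -> None:
        if not 0.0 <= self.zenith <= 180.0:
            raise ValueError("zenith must lie in [0, 180]")
        if not 0.0 <= self.phase_angle <= 180.0:
            raise ValueError("phase angle must lie in [0, 180]")


def toa_solar(day_of_year: int, config: SolarConfig | None = None) -> SpectralIrradiance:
    """Top-of-atmosphere solar spectrum for a day of year.

    I0(lambda) = H0(lambda) * [1 + eps * cos(2*pi*(D - 3)/365)]^2; the
    denominator is 365 for every year.
    """
    if not 1 <= day_of_year <= 366:
        raise ValueError("day_of_year must lie in [1, 366]")
    cfg = config or SolarConfig()
    factor = (1.0 + cfg.eccentricity
              * np.cos(2.0 * np.pi * (day_of_year - 3) / 365.0)) ** 2
    return SpectralIrradiance(cfg.wavelengths, cfg.h0 * factor,
                              np.zeros_like(cfg.h0))


def solar_noon_zenith(latitude: float, day_of_year: int) -> float:
    """Solar zenith angle (deg) at local solar noon; >= 90 means the sun
    never clears the horizon that day."""
    if abs(latitude) > 90:
        raise ValueError("latitude must lie in [-90, 90]")
    return abs(latitude - ephemeris.solar_declination(day_of_year))


def _air_masses(zenith: float, pressure_hpa: float) -> tuple[float, float, float]:
    theta = min(zenith, 89.999)
    mu = np.cos(np.radians(theta))
    M = 1.0 / (mu + 0.15 * (93.885 - theta) ** -1.253)
    Mp = M * pressure_hpa / 1013.25
    Moz = 1.0035 / np.sqrt(mu * mu + 0.007)
    return M, Mp, Moz


def gregg_carder_surface(
    toa: SpectralIrradiance, zenith: float, atmo: AtmosphereParams | None = None
) -> SpectralIrradiance:
    """Clear-sky above-surface spectrum from a TOA spectrum and zenith angle.

    Direct beam: TOA * cos(zenith) * T_rayleigh * T_aerosol * T_ozone *
    T_oxygen * T_water.  Diffuse: single-scattering Rayleigh (half the
    scattered flux reaches the surface) plus forward-scattered aerosol.
    A luminary at or below the horizon yields an all-zero spectrum.
    """
    atmo = atmo or AtmosphereParams()
    lam_nm = toa.wavelengths
    zero = np.zeros_like(lam_nm)
    if zenith >= 90.0:
        return SpectralIrradiance(lam_nm, zero, zero.copy())

    M, Mp, Moz = _air_masses(zenith, atmo.pressure_hpa)
    mu = np.cos(np.radians(zenith))
    lam_um = lam_nm / 1000.0

    gases = _gas_absorption()
    a_oz = np.interp(lam_nm, gases["wavelength"], gases["a_ozone"])
    a_w = np.interp(lam_nm, gases["wavelength"], gases["a_water"])
    a_o = np.interp(lam_nm, gases["wavelength"], gases["a_oxygen"])

    Tr = np.exp(-Mp / (115.6406 * lam_um**4 - 1.335 * lam_um**2))
    Toz = np.exp(-a_oz * (atmo.ozone_du / 1000.0) * Moz)
    To = np.exp(-1.41 * a_o * Mp / (1.0 + 118.3 * a_o * Mp) ** 0.45)
    Tw = np.exp(-0.2385 * a_w * atmo.water_vapor_cm * M
                / (1.0 + 20.07 * a_w * atmo.water_vapor_cm * M) ** 0.45)

    tau_a = atmo.aerosol_tau_550 * (lam_nm / 550.0) ** (-atmo.angstrom_exponent)
    Ta = np.exp(-tau_a * M)
    omega = atmo.single_scatter_albedo
    Taa = np.exp(-(1.0 - omega) * tau_a * M)
    Tas = np.exp(-omega * tau_a * M)

    # aerosol forward-scattering probability from the asymmetry parameter
    b3 = np.log(1.0 - atmo.asymmetry)
    b1 = b3 * (1.459 + b3 * (0.1595 + 0.4129 * b3))
    b2 = b3 * (0.0783 + b3 * (-0.3824 - 0.5874 * b3))
    Fa = 1.0 - 0.5 * np.exp((b1 + b2 * mu) * mu)

    f0 = toa.direct  # TOA beam (the TOA spectrum carries no diffuse part)
    direct = f0 * mu * Tr * Ta * Toz * To * Tw
    diff_r = f0 * mu * Toz * To * Tw * Taa * 0.5 * (1.0 - Tr**0.95)
    diff_a = f0 * mu * Toz * To * Tw * Taa * Tr**1.5 * (1.0 - Tas) * Fa
    return SpectralIrradiance(lam_nm, direct, diff_r + diff_a)


def lumme_bowell_phase(phase_angle: float, slope_parameter: float = 0.08) -> float:
    """Disk-integrated phase factor, normalized to 1 at opposition.

    Uses the two-term analytic phase functions of the H,G system (Bowell's
    fit to the Lumme-Bowell scattering theory); ``slope_parameter`` is G.
    Monotonically non-increasing over [0, 90].
    """
    if not 0.0 <= phase_angle <= 180.0:
        raise ValueError("phase angle must lie in [0, 180]")
    a = np.radians(min(phase_angle, 179.9))
    t = np.tan(a / 2.0)
    phi1 = np.exp(-3.33 * t**0.63)
    phi2 = np.exp(-1.87 * t**1.22)
    g = slope_parameter
    return float((1.0 - g) * phi1 + g * phi2)


def lunar_toa(
    toa_sun: SpectralIrradiance, geometry: LunarGeometry,
    config: LunarConfig | None = None,
) -> SpectralIrradiance:
    """TOA lunar spectrum from the solar one: Lambertian-disk reflection.

    E_moon = E_sun * A(lambda) * f(alpha) * theta_s^2 with theta_s in
    radians (disk radiance L = A E_sun / pi over solid angle pi theta_s^2).
    """
    cfg = config or LunarConfig()
    albedo = cfg.albedo_at(toa_sun.wavelengths)
    f = lumme_bowell_phase(geometry.phase_angle, cfg.slope_parameter)
    theta_s = np.radians(cfg.semi_diameter_deg)
    scale = f * theta_s**2
    return SpectralIrradiance(toa_sun.wavelengths, toa_sun.direct * albedo * scale,
                              toa_sun.diffuse * albedo * scale)


def lunar_geometry(latitude: float, longitude: float,
                   instant: dt.datetime) -> LunarGeometry:
    """Lunar zenith and phase angle for an observer at one instant."""
    jd = ephemeris.julian_day(instant)
    alt = ephemeris.moon_altitude(latitude, longitude, jd)
    return LunarGeometry(zenith=90.0 - alt,
                         phase_angle=ephemeris.phase_angle(jd),
                         instant=instant)


def monthly_culmination(latitude: float, longitude: float, month: int,
                        year: int) -> tuple[dt.date, dt.datetime]:
    """Full-moon date of the month and the culmination instant on that date."""
    if not 1 <= month <= 12:
        raise ValueError("month must lie in [1, 12]")
    fm = ephemeris.full_moon_instant(year, month)
    cul = ephemeris.culmination_instant(latitude, longitude, fm.date())
    return fm.date(), cul


def band_integrate(spectrum: SpectralIrradiance, lo: float = 485.0,
                   hi: float = 495.0) -> float:
    """Trapezoidal integral of the global spectrum over [lo, hi] nm."""
    w = spectrum.wavelengths
    if lo < w[0] or hi > w[-1] or lo >= hi:
        raise ValueError("band must lie within the spectral support")
    total = spectrum.global_
    xs = np.unique(np.concatenate([[lo, hi], w[(w > lo) & (w < hi)]]))
    ys = np.interp(xs, w, total)
    return float(np.trapezoid(ys, xs))


_MID_MONTH_DOY = [15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349]


@dataclass
class SurfaceIrradianceField:
    """Band-integrated (485-495 nm) sun and full-moon surface irradiance
    per latitude and month, W m^-2."""

    latitudes: np.ndarray
    months: np.ndarray
    sun_band: np.ndarray   # (n_lat, 12)
    moon_band: np.ndarray  # (n_lat, 12)
    year: int = 2022
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.sun_band = np.asarray(self.sun_band, dtype=float)
        self.moon_band = np.asarray(self.moon_band, dtype=float)
        if np.any(self.sun_band < 0) or np.any(self.moon_band < 0):
            raise ValueError("band irradiances must be nonnegative")
        # moonlight is bounded by co-located sunlight wherever the sun rises
        # at all; polar-night months legitimately have moon > sun = 0
        lit = self.sun_band > 0
        if np.any(self.moon_band[lit] > self.sun_band[lit]):
            raise ValueError("moonlight cannot exceed co-located sunlight")

    def to_dataframe(self) -> pd.DataFrame:
        lat = np.repeat(self.latitudes, len(self.months))
        mon = np.tile(self.months, len(self.latitudes))
        return pd.DataFrame({
            "latitude": lat, "month": mon,
            "sun_band_w_m2": self.sun_band.ravel(),
            "moon_band_w_m2": self.moon_band.ravel(),
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, year: int = 2022) -> "SurfaceIrradianceField":
        lats = np.unique(df["latitude"])
        piv_s = df.pivot(index="latitude", columns="month", values="sun_band_w_m2")
        piv_m = df.pivot(index="latitude", columns="month", values="moon_band_w_m2")
        piv_s = piv_s.reindex(lats)
        piv_m = piv_m.reindex(lats)
        return cls(lats, piv_s.columns.to_numpy(int), piv_s.to_numpy(),
                   piv_m.to_numpy(), year=year)

    def interp_rows(self, latitudes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-latitude lookup of (sun, moon) bands for arbitrary
        latitudes; returns arrays of shape (len(latitudes), 12)."""
        idx = np.abs(self.latitudes[None, :] - np.asarray(latitudes)[:, None]).argmin(axis=1)
        return self.sun_band[idx], self.moon_band[idx]


def surface_irradiance_field(
    latitudes: np.ndarray,
    year: int = 2022,
    solar_cfg: SolarConfig | None = None,
    lunar_cfg: LunarConfig | None = None,
    atmo: AtmosphereParams | None = None,
) -> SurfaceIrradianceField:
    """Monthly maximum sun and full-moon band irradiance per latitude.

    Sunlight is evaluated on the 15th of each month at solar noon (the
    longitude-free minimum daily zenith).  Moonlight is evaluated at the
    full-moon culmination at longitude 0: the culmination instant and the
    Moon's declination, distance and phase are computed once per month and
    the zenith angle then varies with latitude as |lat - dec| plus the
    topocentric parallax correction.  Below-horizon cases are exactly zero.
    """
    latitudes = np.asarray(latitudes, dtype=float)
    solar_cfg = solar_cfg or SolarConfig()
    lunar_cfg = lunar_cfg or LunarConfig()
    atmo = atmo or AtmosphereParams()
    months = np.arange(1, 13)
    sun = np.zeros((len(latitudes), 12))
    moon = np.zeros((len(latitudes), 12))
    meta: dict = {"full_moon": {}, "culmination": {}}

    for j, month in enumerate(months):
        doy = _MID_MONTH_DOY[month - 1]
        toa = toa_solar(doy, solar_cfg)
        for i, lat in enumerate(latitudes):
            zen = solar_noon_zenith(lat, doy)
            if zen < 90.0:
                sun[i, j] = band_integrate(gregg_carder_surface(toa, zen, atmo))

        fm_date, cul = monthly_culmination(0.0, 0.0, month, year)
        jd = ephemeris.julian_day(cul)
        mlon, mlat, dist = ephemeris.moon_ecliptic(jd)
        _, dec = ephemeris._ecliptic_to_equatorial(mlon, mlat, jd)
        parallax = np.degrees(np.arcsin(ephemeris._EARTH_RADIUS_KM / dist))
        geom_any = LunarGeometry(0.0, ephemeris.phase_angle(jd), cul)
        toa_moon = lunar_toa(toa_solar(cul.timetuple().tm_yday, solar_cfg),
                             geom_any, lunar_cfg)
        meta["full_moon"][int(month)] = fm_date.isoformat()
        meta["culmination"][int(month)] = cul.isoformat()
        for i, lat in enumerate(latitudes):
            alt = 90.0 - abs(lat - dec)
            alt -= parallax * np.cos(np.radians(alt))
            zen = 90.0 - alt
            if zen < 90.0:
                moon[i, j] = band_integrate(gregg_carder_surface(toa_moon, zen, atmo))

    return SurfaceIrradianceField(latitudes, months, sun, moon, year=year, meta=meta)
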