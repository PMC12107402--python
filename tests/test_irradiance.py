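"""Solar/lunar irradiance models: orbital correction, clear-sky atmosphere,
phase curve, lunar disk assembly, band integration, and the monthly field."""

import datetime as dt

import numpy as np
import pytest

from oceandark.irradiance import (AtmosphereParams, LunarConfig, LunarGeometry,
                                  SolarConfig, band_integrate,
                                  gregg_carder_surface, lumme_bowell_phase,
                                  lunar_toa, solar_noon_zenith,
                                  surface_irradiance_field, toa_solar,
                                  SpectralIrradiance)


class TestToaSolar:
    def test_factor_unity_where_cosine_vanishes(self):
        # D = 3 + 365/4 is a zero of cos(2 pi (D-3)/365)
        cfg = SolarConfig(eccentricity=0.0167)
        toa = toa_solar(int(round(3 + 365 / 4)), cfg)
        assert np.allclose(toa.direct / cfg.h0, 1.0, atol=2e-4)

    def test_perihelion_factor_is_annual_maximum(self):
        cfg = SolarConfig(eccentricity=0.0167)
        f3 = toa_solar(3, cfg).direct[0] / cfg.h0[0]
        assert f3 == pytest.approx((1 + 0.0167) ** 2, rel=1e-12)
        others = [toa_solar(d, cfg).direct[0] / cfg.h0[0] for d in range(1, 366)]
        assert f3 == pytest.approx(max(others), rel=1e-6)

    def test_factor_bounded_by_eccentricity(self):
        cfg = SolarConfig(eccentricity=0.0167)
        for d in range(1, 367):
            f = toa_solar(d, cfg).direct[0] / cfg.h0[0]
            assert (1 - 0.0167) ** 2 - 1e-12 <= f <= (1 + 0.0167) ** 2 + 1e-12

    def test_day_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            toa_solar(0)


class TestSolarNoonZenith:
    def test_equator_equinox_overhead(self):
        assert solar_noon_zenith(0.0, 80) == pytest.approx(0.0, abs=0.6)

    def test_midlatitude_june_solstice(self):
        # |50 - 23.44| at solar noon
        assert solar_noon_zenith(50.0, 172) == pytest.approx(26.56, abs=0.5)

    def test_polar_night_flagged_below_horizon(self):
        assert solar_noon_zenith(80.0, 355) > 90.0


class TestGreggCarder:
    def test_below_horizon_yields_zero_spectrum(self):
        s = gregg_carder_surface(toa_solar(166), 90.0)
        assert np.all(s.direct == 0) and np.all(s.diffuse == 0)

    @pytest.mark.parametrize("zenith", [0.0, 30.0, 60.0, 85.0])
    def test_direct_bounded_by_toa_beam(self, zenith):
        toa = toa_solar(166)
        s = gregg_carder_surface(toa, zenith)
        mu = np.cos(np.radians(zenith))
        assert np.all(s.direct <= toa.direct * mu + 1e-12)

    def test_band_irradiance_decreases_with_zenith(self):
        toa = toa_solar(166)
        bands = [band_integrate(gregg_carder_surface(toa, z))
                 for z in range(0, 81, 20)]
        assert all(a > b for a, b in zip(bands, bands[1:]))

    def test_global_is_direct_plus_diffuse_exactly(self):
        s = gregg_carder_surface(toa_solar(100), 40.0)
        assert np.array_equal(s.global_, s.direct + s.diffuse)

    def test_unphysical_atmosphere_rejected(self):
        with pytest.raises(ValueError):
            AtmosphereParams(rel_humidity_pct=150.0)
        with pytest.raises(ValueError):
            AtmosphereParams(visibility_km=-5.0)


class TestPhaseCurve:
    def test_opposition_normalization(self):
        assert lumme_bowell_phase(0.0) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_decrease_to_quadrature(self):
        f = [lumme_bowell_phase(a) for a in np.linspace(0, 90, 50)]
        assert all(a >= b for a, b in zip(f, f[1:]))
        assert 0.0 < lumme_bowell_phase(5.0) < 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lumme_bowell_phase(-1.0)


class TestLunarToa:
    def test_disk_formula_ratio(self):
        """E_moon/E_sun = A * theta_s^2 at opposition (f = 1)."""
        toa = toa_solar(166)
        geom = LunarGeometry(0.0, 0.0, dt.datetime(2022, 6, 14))
        cfg = LunarConfig(semi_diameter_deg=0.26)
        # pin the albedo to 0.10 across the band for the closed-form check
        cfg.albedo = np.full_like(cfg.albedo, 0.10)
        moon = lunar_toa(toa, geom, cfg)
        expected = 0.10 * np.radians(0.26) ** 2
        assert np.allclose(moon.direct / toa.direct, expected, rtol=1e-12)
        assert expected == pytest.approx(2.0593e-6, rel=1e-3)

    def test_zero_albedo_dark_moon(self):
        toa = toa_solar(166)
        cfg = LunarConfig()
        cfg.albedo = np.zeros_like(cfg.albedo) + 1e-12
        moon = lunar_toa(toa, LunarGeometry(0.0, 0.0, dt.datetime(2022, 6, 14)), cfg)
        assert band_integrate(moon) < 1e-10

    def test_semidiameter_squared_scaling(self):
        toa = toa_solar(166)
        geom = LunarGeometry(0.0, 3.0, dt.datetime(2022, 6, 14))
        small = lunar_toa(toa, geom, LunarConfig(semi_diameter_deg=0.26))
        large = lunar_toa(toa, geom, LunarConfig(semi_diameter_deg=0.52))
        assert band_integrate(large) == pytest.approx(4 * band_integrate(small),
                                                      rel=1e-12)


class TestBandIntegrate:
    def test_rectangle_triangle_and_additivity(self):
        w = np.arange(480.0, 501.0)
        flat = SpectralIrradiance(w, np.ones_like(w), np.zeros_like(w))
        assert band_integrate(flat, 485, 495) == pytest.approx(10.0)
        ramp = SpectralIrradiance(w, np.clip((w - 485) / 10, 0, None),
                                  np.zeros_like(w))
        assert band_integrate(ramp, 485, 495) == pytest.approx(5.0)
        a = band_integrate(flat, 485, 490) + band_integrate(flat, 490, 495)
        assert a == pytest.approx(band_integrate(flat, 485, 495))

    def test_band_outside_support_rejected(self):
        w = np.arange(480.0, 501.0)
        s = SpectralIrradiance(w, np.ones_like(w), np.zeros_like(w))
        with pytest.raises(ValueError):
            band_integrate(s, 400, 495)


class TestSurfaceField:
    @pytest.fixture(scope="class")
    def field(self):
        return surface_irradiance_field(np.arange(-85.0, 86.0, 10.0))

    def test_polar_night_sun_is_zero(self, field):
        i = np.argmin(np.abs(field.latitudes + 85))
        assert field.sun_band[i, 5] == 0.0  # June at 85 S

    def test_all_values_finite_nonnegative(self, field):
        assert np.all(np.isfinite(field.sun_band))
        assert np.all(field.sun_band >= 0)
        assert np.all(np.isfinite(field.moon_band))
        assert np.all(field.moon_band >= 0)

    def test_moonlight_small_fraction_of_sunlight(self, field):
        """Where the noon sun stands at least as high as the culminating
        moon, full-moon irradiance is under 1e-5 of the solar value."""
        lit = (field.sun_band > 0) & (field.moon_band > 0)
        # conservative sub-selection: strong sun (upper half of its range)
        strong = field.sun_band > 0.5 * field.sun_band.max()
        sel = lit & strong
        assert sel.any()
        assert np.all(field.moon_band[sel] / field.sun_band[sel] <= 1e-5)

    def test_declination_mirror_symmetry_without_eccentricity(self):
        fld = surface_irradiance_field(
            np.array([-60.0, -45.0, -15.0, 15.0, 45.0, 60.0]),
            solar_cfg=SolarConfig(eccentricity=0.0))
        lats = fld.latitudes
        for phi in (15.0, 45.0, 60.0):
            a = fld.sun_band[np.argmin(np.abs(lats - phi)), 5]    # June
            b = fld.sun_band[np.argmin(np.abs(lats + phi)), 11]   # December
            assert a == pytest.approx(b, rel=0.05)

    def test_roundtrip_through_dataframe(self, field):
        from oceandark.irradiance import SurfaceIrradianceField

        df = field.to_dataframe()
        back = SurfaceIrradianceField.from_dataframe(df)
        assert np.allclose(back.sun_band, field.sun_band)
        assert np.allclose(back.moon_band, field.moon_band)
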