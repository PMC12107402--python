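"""Area engine and area-based summaries: conservation, nesting, ranking."""

import numpy as np
import pandas as pd
import pytest

from oceandark.aggregate import (EARTH_RADIUS_KM, cell_area_field, delta_histogram,
                                 pixel_area, region_trend_summary, threshold_areas)
from oceandark.grids import GridSpec, RegionMask


class TestPixelArea:
    def test_equatorial_one_degree_cell(self):
        grid = GridSpec.global_grid(1.0)
        a = pixel_area(0.5, grid)  # cell spanning 0..1 degree
        assert a == pytest.approx(12364.0, rel=1e-3)

    def test_spherical_sum_is_earth_area(self):
        grid = GridSpec.global_grid(1.0)
        total = cell_area_field(grid).sum()
        assert total == pytest.approx(4 * np.pi * EARTH_RADIUS_KM**2, rel=1e-3)

    def test_mercator_grid_cosine_footprint(self):
        grid = GridSpec.global_grid(1.0)
        a = pixel_area(60.0, grid, mode="mercator_grid", spacing_m=9000.0)
        assert a == pytest.approx((9.0 * 0.5) ** 2, rel=1e-12)

    def test_pole_degenerates_to_zero(self):
        grid = GridSpec.global_grid(1.0)
        assert pixel_area(90.0, grid, mode="mercator_grid") == pytest.approx(0.0, abs=1e-12)
        assert pixel_area(89.5, grid) > 0

    def test_modes_agree_on_regional_totals_at_low_latitude(self):
        """Mercator points are denser on the ground at latitude, which
        exactly compensates the cos^2 footprint: summed footprints over a
        low-latitude band match the true spherical area within 1%."""
        from oceandark.geotiff import mercator_point_grid

        grid = GridSpec(30, 10, -15.0, 15.0, 0.0, 10.0, 1.0)
        lats, _ = mercator_point_grid(grid, spacing_m=9000.0)
        merc_total = sum(pixel_area(lat, grid, mode="mercator_grid",
                                    spacing_m=9000.0) for lat in lats)
        spherical_total = cell_area_field(grid).sum()
        assert merc_total == pytest.approx(spherical_total, rel=0.01)


def _two_region_mask(grid: GridSpec) -> RegionMask:
    rid = np.zeros(grid.shape, dtype=int)
    rid[:, grid.n_cols // 2:] = 1
    return RegionMask(grid, rid, {0: "West", 1: "East"})


class TestRegionSummary:
    @pytest.fixture(scope="class")
    def grid(self):
        return GridSpec(8, 8, -16.0, 16.0, -16.0, 16.0, 4.0)

    def test_pure_increasing_region_is_100pct_and_first(self, grid):
        cls = np.zeros(grid.shape, dtype=int)
        cls[:, : grid.n_cols // 2] = 1  # all of region West increases
        summary = region_trend_summary(cls, _two_region_mask(grid))
        top = summary.table.iloc[0]
        assert top["region_name"] == "West"
        assert top["pct_increasing"] == pytest.approx(100.0)
        assert summary.table.iloc[1]["pct_increasing"] == 0.0

    def test_areas_conserved_over_partition(self, grid):
        cls = np.random.default_rng(0).choice([-1, 0, 1], grid.shape)
        summary = region_trend_summary(cls, _two_region_mask(grid))
        total = summary.table["total_area_km2"].sum()
        assert total == pytest.approx(cell_area_field(grid).sum(), rel=1e-12)
        per_class = (summary.table["area_increasing_km2"]
                     + summary.table["area_decreasing_km2"]
                     + summary.table["area_no_change_km2"]).sum()
        assert per_class == pytest.approx(total, rel=1e-12)

    def test_insufficient_pixels_out_of_denominator(self, grid):
        cls = np.full(grid.shape, -9)
        cls[0, 0] = 1
        summary = region_trend_summary(cls, _two_region_mask(grid))
        west = summary.table.set_index("region_name").loc["West"]
        assert west["pct_increasing"] == pytest.approx(100.0)
        assert west["area_insufficient_km2"] > 0


class TestThresholdAreas:
    def test_hand_built_thresholds(self):
        grid = GridSpec(1, 3, 0.0, 1.0, 0.0, 3.0, 1.0)
        dz = np.array([[-5.0, -15.0, -55.0]])
        t = threshold_areas(dz, grid=grid)
        areas = cell_area_field(grid)[0]
        t = t.set_index("threshold")
        assert t.loc[">10 m", "area_km2"] == pytest.approx(areas[1] + areas[2])
        assert t.loc[">50 m", "area_km2"] == pytest.approx(areas[2])
        assert t.loc[">100 m", "area_km2"] == 0.0

    def test_zero_delta_zero_areas(self):
        grid = GridSpec(2, 2, 0.0, 2.0, 0.0, 2.0, 1.0)
        t = threshold_areas(np.zeros(grid.shape), grid=grid)
        assert (t["area_km2"] == 0).all()

    def test_nesting_property(self):
        grid = GridSpec(10, 10, -5.0, 5.0, 0.0, 10.0, 1.0)
        dz = -np.random.default_rng(1).uniform(0, 200, grid.shape)
        t = threshold_areas(dz, grid=grid).set_index("threshold")
        assert (t.loc[">100 m", "area_km2"] <= t.loc[">50 m", "area_km2"]
                <= t.loc[">10 m", "area_km2"])

    def test_strict_comparison_at_boundary(self):
        grid = GridSpec(1, 1, 0.0, 1.0, 0.0, 1.0, 1.0)
        t = threshold_areas(np.array([[-50.0]]), grid=grid).set_index("threshold")
        assert t.loc[">50 m", "area_km2"] == 0.0  # "more than", strictly
        assert t.loc[">10 m", "area_km2"] > 0


class TestDeltaHistogram:
    def test_single_pixel_lands_in_correct_bin(self):
        grid = GridSpec(1, 1, 0.0, 1.0, 0.0, 1.0, 1.0)
        h = delta_histogram(np.array([[-15.0]]), grid=grid)
        assert len(h) == 1
        assert (h.iloc[0]["bin_low_m"], h.iloc[0]["bin_high_m"]) == (10.0, 20.0)
        assert h.iloc[0]["direction"] == "reduction"

    def test_bin_boundary_is_left_open(self):
        grid = GridSpec(1, 1, 0.0, 1.0, 0.0, 1.0, 1.0)
        h = delta_histogram(np.array([[-10.0]]), grid=grid)
        assert (h.iloc[0]["bin_low_m"], h.iloc[0]["bin_high_m"]) == (0.0, 10.0)

    def test_histogram_conserves_nonzero_area(self):
        grid = GridSpec(10, 10, -5.0, 5.0, 0.0, 10.0, 1.0)
        rng = np.random.default_rng(2)
        dz = rng.uniform(-120, 30, grid.shape)
        dz[0, :3] = 0.0
        h = delta_histogram(dz, grid=grid)
        areas = cell_area_field(grid)
        assert h["area_km2"].sum() == pytest.approx(areas[dz != 0].sum(), rel=1e-12)

    def test_empty_raster_empty_histogram(self):
        grid = GridSpec(2, 2, 0.0, 2.0, 0.0, 2.0, 1.0)
        h = delta_histogram(np.zeros(grid.shape), grid=grid)
        assert h.empty
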