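"""Configuration and the end-to-end pipeline driver.

Stages: simulate (optional) -> trend -> irradiance -> photic -> aggregate.
Every stage writes its artifacts into the output directory and a JSON
provenance record (config hash, seed, package versions) accompanies each
run; re-running with the same config and seed reproduces every numeric
output bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .aggregate import delta_histogram, region_trend_summary, threshold_areas
from .geotiff import read_raster, read_raster_stack, write_raster, write_stack
from .grids import GridSpec, BathymetryGrid, RegionMask
from .irradiance import (AtmosphereParams, LunarConfig, SolarConfig,
                         SurfaceIrradianceField, surface_irradiance_field)
from .photic import PhoticConfig, delta_field
from .synthetic import TrendScenario, generate_bathymetry, generate_kd_stack, generate_region_masks
from .trend import CLASS_CODES, KdTrendModel

log = logging.getLogger("oceandark")

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs; YAML keys mirror the field names."""

    output_dir: str = "oceandark_out"
    seed: int = 0
    workers: int = 1
    years: tuple[int, int] = (2003, 2022)

    # simulate stage (used when kd_stack_path is empty)
    simulate: bool = True
    grid_rows: int = 32
    grid_cols: int = 32
    lat_min: float = -64.0
    lat_max: float = 64.0
    lon_min: float = -64.0
    lon_max: float = 64.0
    baseline_kd: float = 0.1
    trend_slope: float = 0.002
    trend_block_fraction: float = 0.25   # planted darkening block edge fraction
    ar1_phi: float = 0.5
    noise_sigma: float = 0.005
    missing_fraction: float = 0.05
    n_regions: int = 6
    shelf_depth: float = 50.0
    abyss_depth: float = 4000.0

    # externally supplied inputs (override simulation)
    kd_stack_path: str = ""
    bathymetry_path: str = ""

    # trend stage
    min_valid_years: int = 10
    ci_level: float = 0.95
    arima_max_p: int = 2
    arima_max_q: int = 2
    engine: str = "css"

    # irradiance stage
    eccentricity: float = 0.0167
    irradiance_year: int = 2022
    atmosphere: dict = field(default_factory=dict)   # AtmosphereParams overrides
    semi_diameter_deg: float = 0.26

    # photic stage
    i_sens_uw_m2: float = 0.027      # Calanus DVM threshold, uW m^-2
    definition: str = "threshold"    # or one_percent
    luminaries: tuple[str, ...] = ("sun", "moon")

    # aggregation stage
    area_mode: str = "spherical"     # or mercator_grid
    mercator_spacing_m: float = 9000.0
    bin_width_m: float = 10.0

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if y1 <= y0:
            raise ValueError("years must be an increasing (start, end) pair")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")

    @property
    def year_array(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)

    def grid(self) -> GridSpec:
        cell = (self.lat_max - self.lat_min) / self.grid_rows
        return GridSpec(self.grid_rows, self.grid_cols, self.lat_min,
                        self.lat_max, self.lon_min,
                        self.lon_min + cell * self.grid_cols, cell)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML config (all keys optional) and apply overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as f:
            data = yaml.safe_load(f) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    for key in ("years", "luminaries"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def _regions_to_geojson(mask: RegionMask, path: Path) -> None:
    from shapely.geometry import box, mapping
    from shapely.ops import unary_union

    grid = mask.grid
    lat_e = grid.lat_edges
    lon_e = np.linspace(grid.lon_min, grid.lon_max, grid.n_cols + 1)
    features = []
    for rid in mask.ids:
        rows, cols = np.nonzero(mask.region_id == rid)
        boxes = [box(lon_e[c], lat_e[r + 1], lon_e[c + 1], lat_e[r])
                 for r, c in zip(rows, cols)]
        geom = unary_union(boxes)
        features.append({"type": "Feature",
                         "properties": {"region_id": int(rid),
                                        "name": mask.names[int(rid)]},
                         "geometry": mapping(geom)})
    path.write_text(json.dumps({"type": "FeatureCollection",
                                "features": features}))


def _stage_simulate(cfg: PipelineConfig, out: Path):
    grid = cfg.grid()
    slope = np.zeros(grid.shape)
    nb = max(int(round(cfg.trend_block_fraction * grid.n_rows)), 1)
    mb = max(int(round(cfg.trend_block_fraction * grid.n_cols)), 1)
    slope[:nb, :mb] = cfg.trend_slope   # planted darkening block, NW corner
    scenario = TrendScenario(baseline_kd=cfg.baseline_kd, slope=slope,
                             ar1_phi=cfg.ar1_phi, noise_sigma=cfg.noise_sigma,
                             years=cfg.year_array, seed=cfg.seed,
                             missing_fraction=cfg.missing_fraction)
    stack, truth = generate_kd_stack(grid, scenario)
    bathy = generate_bathymetry(grid, cfg.shelf_depth, cfg.abyss_depth,
                                seed=cfg.seed + 1)
    regions = generate_region_masks(grid, cfg.n_regions, seed=cfg.seed + 2)

    write_stack(out / "kd_stack.tif", stack)
    write_raster(out / "bathymetry.tif", grid, bathy.depth, ["depth_m"])
    write_raster(out / "regions.tif", grid, regions.region_id.astype(np.float32),
                 ["region_id"])
    write_raster(out / "truth.tif", grid,
                 np.stack([truth.slope, truth.classification.astype(float)]),
                 ["slope_true", "classification_true"])
    _regions_to_geojson(regions, out / "regions.geojson")
    sidecar = {"scenario": {"baseline_kd": cfg.baseline_kd,
                            "trend_slope": cfg.trend_slope,
                            "block_rows": nb, "block_cols": mb,
                            "ar1_phi": cfg.ar1_phi,
                            "noise_sigma": cfg.noise_sigma,
                            "missing_fraction": cfg.missing_fraction,
                            "seed": cfg.seed}}
    (out / "scenario.yaml").write_text(yaml.safe_dump(sidecar))
    return stack, bathy, regions, truth


def _stage_trend(cfg: PipelineConfig, out: Path, stack):
    orders = tuple(sorted(((p, q) for p in range(cfg.arima_max_p + 1)
                           for q in range(cfg.arima_max_q + 1)),
                          key=lambda pq: (sum(pq), pq)))
    model = KdTrendModel(stack, min_valid_years=cfg.min_valid_years,
                         orders=orders, ci_level=cfg.ci_level, engine=cfg.engine)
    results = model.fit(workers=cfg.workers)
    bands = np.stack([results.slope, results.ci_low, results.ci_high,
                      results.classification.astype(float),
                      results.kd_start, results.kd_end,
                      results.n_valid.astype(float)])
    write_raster(out / "trend.tif", stack.grid, bands,
                 ["slope", "ci_low", "ci_high", "classification",
                  "kd_start", "kd_end", "n_valid"])
    results.to_dataframe().to_csv(out / "trend_summary.csv", index=False)
    (out / "trend_summary.txt").write_text(results.summary() + "\n")
    return results


def _stage_irradiance(cfg: PipelineConfig, out: Path, grid: GridSpec):
    atmo = AtmosphereParams(**cfg.atmosphere)
    fld = surface_irradiance_field(grid.lat_centers, year=cfg.irradiance_year,
                                   solar_cfg=SolarConfig(cfg.eccentricity),
                                   lunar_cfg=LunarConfig(cfg.semi_diameter_deg),
                                   atmo=atmo)
    fld.to_dataframe().to_csv(out / "irradiance.csv", index=False)
    return fld


def _stage_photic(cfg: PipelineConfig, out: Path, results, fld, bathy):
    pcfg = PhoticConfig.from_microwatts(cfg.i_sens_uw_m2, cfg.definition)
    pz = delta_field(results.kd_start, results.kd_end, fld, bathy, pcfg,
                     luminaries=cfg.luminaries)
    for lum in cfg.luminaries:
        bands = np.stack([pz.annual_mean_z(lum, "start"),
                          pz.annual_mean_z(lum, "end"),
                          pz.delta_z[lum], pz.pct_change[lum],
                          pz.clipped_fraction[lum]])
        write_raster(out / f"photic_{lum}.tif", pz.grid, bands,
                     ["z_start_mean", "z_end_mean", "delta_z", "pct_change",
                      "clipped_fraction"])
    return pz


def _stage_aggregate(cfg: PipelineConfig, out: Path, results, pz, regions):
    summary = region_trend_summary(results.classification, regions,
                                   mode=cfg.area_mode,
                                   spacing_m=cfg.mercator_spacing_m)
    summary.table.to_csv(out / "regions_ranked.csv", index=False)
    thr_frames, hist_frames = [], []
    for lum in cfg.luminaries:
        t = threshold_areas(pz, mode=cfg.area_mode,
                            spacing_m=cfg.mercator_spacing_m, luminary=lum)
        t.insert(0, "luminary", lum)
        thr_frames.append(t)
        hist_frames.append(delta_histogram(pz, bin_width=cfg.bin_width_m,
                                           mode=cfg.area_mode,
                                           spacing_m=cfg.mercator_spacing_m,
                                           luminary=lum))
    import pandas as pd

    pd.concat(thr_frames, ignore_index=True).to_csv(out / "thresholds.csv", index=False)
    pd.concat(hist_frames, ignore_index=True).to_csv(out / "histogram.csv", index=False)
    return summary


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages; returns the artifact directory."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    if not cfg.simulate:  # pre-flight path checks before any compute
        for p in (cfg.kd_stack_path, cfg.bathymetry_path):
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p!r}")

    timers: dict[str, float] = {}

    def timed(name, fn, *args):
        t0 = time.time()
        res = fn(*args)
        timers[name] = round(time.time() - t0, 3)
        log.info("stage %s done in %.2f s", name, timers[name])
        return res

    if cfg.simulate:
        stack, bathy, regions, _ = timed("simulate", _stage_simulate, cfg, out)
    else:
        stack = read_raster_stack(cfg.kd_stack_path, list(cfg.year_array))
        g, b, _ = read_raster(cfg.bathymetry_path)
        bathy = BathymetryGrid(grid=g, depth=b[0])
        g2, r, _ = read_raster(Path(cfg.kd_stack_path).parent / "regions.tif")
        regions = RegionMask(grid=g2, region_id=np.nan_to_num(r[0], nan=-1).astype(int),
                             names={})

    results = timed("trend", _stage_trend, cfg, out, stack)
    fld = timed("irradiance", _stage_irradiance, cfg, out, stack.grid)
    pz = timed("photic", _stage_photic, cfg, out, results, fld, bathy)
    timed("aggregate", _stage_aggregate, cfg, out, results, pz, regions)

    import pandas, scipy, statsmodels, tifffile

    provenance = {
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_seconds": timers,
        "total_seconds": round(time.time() - t_start, 3),
        "versions": {"oceandark": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pandas.__version__,
                     "statsmodels": statsmodels.__version__,
                     "tifffile": tifffile.__version__},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return out
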