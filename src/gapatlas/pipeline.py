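"""End-to-end orchestration with a single declarative configuration.

A run executes: (optional) synthetic-world simulation → grid build and
spatial join → climatic clustering → per-species ecological profiles → gap
analysis → summary tables, writing a manifest with the configuration hash
and seed so identical configurations produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import climate_clustering as cc
from . import ecological_profiles as ep
from . import gap_analysis as ga
from . import geodata_io as gio
from . import summaries as sm
from . import synthetic_data as sd

logger = logging.getLogger("gapatlas")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults are the study conventions
    (10′ grid, 1 km AOO, theta = 0.10, two components, 17/12% targets)."""

    out_dir: str = "gapatlas_out"
    seed: int = 0
    simulate: bool = True
    # paths used when simulate is False
    occurrences_path: str | None = None
    attributes_path: str | None = None
    boundary_path: str | None = None
    regions_path: str | None = None
    protected_areas_path: str | None = None
    raster_dir: str | None = None
    # synthetic-world conditions
    extent: tuple[float, float, float, float] = (52.0, 16.0, 54.0, 18.0)
    resolution: float = 0.01
    n_regions: int = 5
    n_protected: int = 12
    protected_coverage_fraction: float = 0.04
    n_species: int = 30
    records_per_species: tuple[int, int] = (3, 60)
    effort_bias: float = 1.0
    # analysis settings
    grid_cell_arcmin: float = 10.0
    aoo_resolutions: tuple[float, ...] = (1.0, 4.0)
    theta: float = 0.10
    retained_components: int = 2
    altitude_filter_mode: str = "observed-range"
    targets: tuple[float, ...] = (17.0, 12.0)
    log_level: str = "INFO"

    def validate(self) -> None:
        for t in self.targets:
            if not (0 < t <= 100):
                raise ValueError(f"target {t} outside (0, 100]")
        if not self.simulate:
            for name in ("occurrences_path", "attributes_path", "boundary_path",
                         "protected_areas_path", "raster_dir"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"config {name} = {p!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        for name in ("extent", "records_per_species", "aoo_resolutions", "targets"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _load_world(cfg: RunConfig) -> tuple[sd.SyntheticWorld | None, gio.OccurrenceTable, "object"]:
    if cfg.simulate:
        world = sd.generate_world(cfg.seed, cfg.extent, cfg.resolution, cfg.n_regions,
                                  cfg.n_protected, cfg.protected_coverage_fraction)
        occ, truth = sd.generate_species(world, cfg.seed, cfg.n_species,
                                         cfg.records_per_species, cfg.effort_bias)
        return world, occ, truth.attributes
    occ = gio.read_occurrences(cfg.occurrences_path)
    attrs = gio.read_species_attributes(cfg.attributes_path)
    rdir = Path(cfg.raster_dir)
    bioclim = {k: gio.read_raster(rdir / f"{k}.asc") for k in sd.BIOCLIM_KEYS}
    world = sd.SyntheticWorld(
        seed=cfg.seed,
        extent=gio.read_polygons(cfg.boundary_path).union().bounds,
        elevation=gio.read_raster(rdir / "elevation.asc"),
        bioclim=bioclim,
        landcover=gio.read_raster(rdir / "landcover.asc", kind="categorical"),
        boundary=gio.read_polygons(cfg.boundary_path),
        regions=gio.read_polygons(cfg.regions_path) if cfg.regions_path else gio.PolygonSet([]),
        protected_areas=gio.read_polygons(cfg.protected_areas_path),
    )
    return world, occ, attrs


def write_world(world: sd.SyntheticWorld, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    gio.write_raster(world.elevation, out / "elevation.asc")
    gio.write_raster(world.landcover, out / "landcover.asc")
    for k, r in world.bioclim.items():
        gio.write_raster(r, out / f"{k}.asc")
    gio.write_polygons(world.boundary, out / "boundary.geojson")
    gio.write_polygons(world.regions, out / "regions.geojson")
    gio.write_polygons(world.protected_areas, out / "protected_areas.geojson")


def run_all(cfg: RunConfig) -> Path:
    """Execute every stage; returns the output directory.

    Any stage failure aborts with the stage name and cause.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    stage = "init"
    try:
        stage = "simulate/load"
        world, occ, attrs = _load_world(cfg)
        if cfg.simulate:
            write_world(world, out / "world")
            gio.write_occurrences(occ, out / "world" / "occurrences.csv")
            gio.write_table(attrs, out / "world" / "attributes.csv", sort_by=["species_id"])

        stage = "grid/join"
        grid = gio.build_grid(world.boundary, cfg.grid_cell_arcmin)
        joined = gio.spatial_join(occ, grid)
        coverage = sm.sampling_coverage(occ, grid)
        (out / "grids").mkdir(exist_ok=True)
        for sp in occ.species:
            gio.write_species_grid(sp, joined.get(sp, set()), grid,
                                   out / "grids" / f"{sp}.geojson")

        stage = "clusters"
        mask = world.boundary_pixel_mask()
        model = cc.fit_pca(world.bioclim, mask, retained=cfg.retained_components)
        part = cc.assign_clusters(model, cc.equal_variance_breakpoints(model, cfg.theta))
        clraster = cc.cluster_raster(model, part, world.elevation)
        gio.write_raster(clraster, out / "clusters.asc")
        model.loadings_table().to_csv(out / "pca_loadings.csv")
        with open(out / "breakpoints.json", "w") as fh:
            json.dump({"theta": part.theta, "origin": part.origin,
                       "bins_per_component": part.bins_per_component,
                       "breakpoints": [b.tolist() for b in part.breakpoints]}, fh, indent=1)
        cov = cc.cluster_coverage(occ, model, part, world.elevation)
        gio.write_table(cov, out / "cluster_coverage.csv", sort_by=["cluster"])

        stage = "profiles"
        (out / "profiles").mkdir(exist_ok=True)
        dist_rasters = ep.class_distance_rasters(world.landcover)
        for sp in occ.species:
            prof = ep.species_profile(sp, occ, world.elevation,
                                      world.bioclim["BIO1"], world.bioclim["BIO12"],
                                      world.landcover, mask, dist_rasters)
            with open(out / "profiles" / f"{sp}.json", "w") as fh:
                json.dump(prof, fh, indent=1, sort_keys=True)

        stage = "gap"
        estimates = ga.species_range_table(occ, world.elevation, world.protected_areas,
                                           filter_mode=cfg.altitude_filter_mode)
        report = ga.gap_report(estimates, attrs, cfg.targets)
        gio.write_table(report.table, out / "gap_species.csv", sort_by=["species_id", "method"])
        with open(out / "gap_counts.json", "w") as fh:
            json.dump(report.counts, fh, indent=1, sort_keys=True)
        aoo4 = [ga.aoo(occ.subset(sp), world.elevation, 4.0) for sp in occ.species]
        gio.write_table(
            pd.DataFrame([{"species_id": e.species_id, "aoo4_km2": e.area_km2,
                               "n_blocks": len(e.pixel_set)} for e in aoo4]),
            out / "aoo_4km.csv", sort_by=["species_id"])

        stage = "summarize"
        rich_cells = sm.richness(occ, grid)
        gio.write_table(rich_cells, out / "richness_cells.csv", sort_by=["unit"])
        if len(world.regions):
            gio.write_table(sm.richness(occ, world.regions, attrs),
                            out / "richness_regions.csv", sort_by=["unit"])
        gio.write_table(sm.pa_representation(occ, attrs, world.protected_areas),
                        out / "pa_representation.csv", sort_by=["subset"])
        gio.write_table(sm.iucn_tally(attrs), out / "iucn_tally.csv")
        with open(out / "sampling_coverage.json", "w") as fh:
            json.dump(coverage, fh, indent=1, sort_keys=True)

        manifest = {"config": asdict(cfg), "config_hash": cfg.digest(),
                    "seed": cfg.seed, "version": __version__,
                    "numpy": np.__version__}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
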