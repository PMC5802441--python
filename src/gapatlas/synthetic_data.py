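"""Self-consistent synthetic study systems with known ground truth.

The generator emulates the layer suite of an arid-country reptile atlas:
smooth, mutually correlated climate surfaces driven by a two-massif
elevation template; a nine-class land-cover mosaic; an irregular country
boundary with administrative regions; protected-area polygons whose areas
span several orders of magnitude; and niche-driven occurrence records with
spatially uneven sampling effort.  Every random draw derives from one root
seed through named child streams, so identical calls are bit-identical.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram

from .geodata_io import (
    LANDCOVER_CLASSES,
    OccurrenceTable,
    PolygonSet,
    RasterLayer,
    pixel_area_km2,
)

logger = logging.getLogger("gapatlas")

BIOCLIM_KEYS = ("BIO1", "BIO4", "BIO5", "BIO6", "BIO7", "BIO10",
                "BIO11", "BIO12", "BIO13", "BIO16", "BIO18", "BIO19")

#: default attribute prevalences (fractions of the species pool)
DEFAULT_PREVALENCES = {
    "endemic": 20 / 101,
    "venomous": 9 / 101,
    "island": 29 / 101,
    "described": 92 / 101,
}
#: default IUCN category mix (counts out of 101)
DEFAULT_IUCN_WEIGHTS = {"NE": 32, "DD": 5, "LC": 32, "LC*": 26, "NT": 1, "VU": 5}
DEFAULT_GROUP_WEIGHTS = {"gecko": 45, "snake": 21, "agamid": 13, "skink": 7,
                         "lacertid": 13, "varanid": 1, "amphisbaenid": 1}


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline is supposed to recover."""

    niches: pd.DataFrame = field(default_factory=pd.DataFrame)
    occupied: dict[str, set[tuple[int, int]]] = field(default_factory=dict)
    aoo_km2: dict[str, float] = field(default_factory=dict)
    percent_protected: dict[str, float] = field(default_factory=dict)
    attributes: pd.DataFrame = field(default_factory=pd.DataFrame)

    def cell_richness(self, grid, world: "SyntheticWorld") -> dict[tuple[int, int], int]:
        """True per-cell species richness: species whose occupied pixels have
        a center inside the cell."""
        counts: dict[tuple[int, int], set[str]] = {}
        lons, lats = world.elevation.centers()
        for sp, pixels in self.occupied.items():
            for r, c in pixels:
                cell = grid.cell_of(float(lons[c]), float(lats[r]))
                if cell is not None:
                    counts.setdefault(cell, set()).add(sp)
        return {cell: len(sps) for cell, sps in counts.items()}


@dataclass
class SyntheticWorld:
    seed: int
    extent: tuple[float, float, float, float]
    elevation: RasterLayer
    bioclim: dict[str, RasterLayer]
    landcover: RasterLayer
    boundary: PolygonSet
    regions: PolygonSet
    protected_areas: PolygonSet
    truth: GroundTruth = field(default_factory=GroundTruth)

    @property
    def resolution(self) -> float:
        return self.elevation.resolution[0]

    def boundary_pixel_mask(self) -> np.ndarray:
        """Boolean array of pixels whose center lies inside the boundary."""
        lons, lats = self.elevation.centers()
        gx, gy = np.meshgrid(lons, lats)
        geom = self.boundary.union()
        shapely.prepare(geom)
        return shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(gx.shape)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Spatially autocorrelated standard field (zero mean, unit sd)."""
    z = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (z - z.mean()) / max(z.std(), 1e-12)


def _blob_polygon(rng: np.random.Generator, cx: float, cy: float, radius: float,
                  irregularity: float = 0.25, n_vertices: int = 48) -> Polygon:
    """Irregular star-convex polygon around (cx, cy)."""
    theta = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    k = rng.integers(2, 5)
    phase = rng.uniform(0, 2 * math.pi, size=3)
    wobble = sum(rng.uniform(0.3, 1.0) * np.sin((k + i) * theta + phase[i]) for i in range(3))
    wobble = wobble / (np.abs(wobble).max() + 1e-12)
    r = radius * (1.0 + irregularity * wobble)
    pts = np.c_[cx + r * np.cos(theta), cy + r * np.sin(theta)]
    poly = Polygon(pts)
    return poly if poly.is_valid else shapely.make_valid(poly)


def generate_world(
    seed: int = 0,
    extent: tuple[float, float, float, float] = (52.0, 16.0, 54.0, 18.0),
    resolution: float = 0.01,
    n_regions: int = 5,
    n_protected: int = 12,
    protected_coverage_fraction: float = 0.04,
) -> SyntheticWorld:
    """Generate the complete layer suite for one synthetic study system.

    Parameters
    ----------
    extent : (west, south, east, north) in decimal degrees.
    resolution : pixel size in degrees (default 0.01° ≈ 36 arc-sec ≈ 1 km).
    protected_coverage_fraction : target fraction of the country covered by
        the protected-area union; must lie in [0, 0.5].
    """
    if not (0.0 <= protected_coverage_fraction <= 0.5):
        raise ValueError("protected_coverage_fraction must be in [0, 0.5]")
    if protected_coverage_fraction > 0 and n_protected < 1:
        raise ValueError("cannot reach positive coverage with zero protected areas")

    w, s, e, n = extent
    ncol = int(round((e - w) / resolution))
    nrow = int(round((n - s) / resolution))
    streams = np.random.SeedSequence(seed).spawn(5)
    rng_terrain, rng_climate, rng_land, rng_poly, rng_pa = (
        np.random.default_rng(ss) for ss in streams
    )

    lons = w + (np.arange(ncol) + 0.5) * resolution
    lats = n - (np.arange(nrow) + 0.5) * resolution
    gx, gy = np.meshgrid(lons, lats)

    # --- elevation: two mountain massifs over a low desert plain ------------
    def massif(cx, cy, sx, sy, height, angle):
        dx, dy = gx - cx, gy - cy
        u = dx * math.cos(angle) + dy * math.sin(angle)
        v = -dx * math.sin(angle) + dy * math.cos(angle)
        return height * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))

    span_x, span_y = e - w, n - s
    elev = 80.0 + 120.0 * _smooth_field(rng_terrain, (nrow, ncol), sigma=max(4, ncol // 20))
    # northern arc-shaped range and a southern coastal plateau
    elev += massif(w + 0.70 * span_x, s + 0.78 * span_y, 0.22 * span_x, 0.09 * span_y, 2300.0, 0.5)
    elev += massif(w + 0.30 * span_x, s + 0.18 * span_y, 0.25 * span_x, 0.07 * span_y, 1400.0, -0.1)
    for _ in range(3):  # minor hills
        elev += massif(rng_terrain.uniform(w, e), rng_terrain.uniform(s, n),
                       0.05 * span_x * rng_terrain.uniform(0.5, 1.5),
                       0.05 * span_y * rng_terrain.uniform(0.5, 1.5),
                       rng_terrain.uniform(150, 500), rng_terrain.uniform(0, math.pi))
    elev = np.clip(elev, 0.0, None)

    def layer(vals, kind="continuous"):
        return RasterLayer(vals, (w, n), (resolution, resolution), nodata=-9999.0, kind=kind)

    # --- bioclim: temperature from a lapse rate, precipitation orographic ---
    bio: dict[str, np.ndarray] = {}
    bio["BIO1"] = 28.0 - 6.5 * elev / 1000.0 + 0.8 * _smooth_field(rng_climate, (nrow, ncol), 8)
    coast_dist = np.minimum(gy - s, e - gx)  # sea along the south and east edges
    monsoon = 160.0 * np.exp(-np.clip(coast_dist, 0, None) / (0.18 * span_y)) * (elev > 300)
    bio["BIO12"] = np.clip(
        25.0 + 0.11 * elev + monsoon + 18.0 * _smooth_field(rng_climate, (nrow, ncol), 10),
        0.0, None,
    )
    amp_hot = 6.0 + 2.0 * (1 + _smooth_field(rng_climate, (nrow, ncol), 12)).clip(0.2, 2.0)
    amp_cold = 7.0 + 2.5 * (1 + _smooth_field(rng_climate, (nrow, ncol), 12)).clip(0.2, 2.0)
    bio["BIO5"] = bio["BIO1"] + amp_hot
    bio["BIO6"] = bio["BIO1"] - amp_cold
    bio["BIO7"] = bio["BIO5"] - bio["BIO6"]
    bio["BIO10"] = bio["BIO1"] + 0.55 * amp_hot
    bio["BIO11"] = bio["BIO1"] - 0.55 * amp_cold
    bio["BIO4"] = 100.0 * (0.8 * amp_cold + 0.6 * amp_hot) \
        + 60.0 * _smooth_field(rng_climate, (nrow, ncol), 9)
    f13 = 0.15 + 0.10 * (0.5 * (1 + _smooth_field(rng_climate, (nrow, ncol), 14))).clip(0, 1)
    bio["BIO13"] = bio["BIO12"] * f13
    bio["BIO16"] = bio["BIO12"] * np.clip(2.4 * f13, None, 0.8)
    f_wet = (0.30 + 0.25 * (0.5 * (1 + _smooth_field(rng_climate, (nrow, ncol), 14)))).clip(0.05, 0.75)
    bio["BIO18"] = bio["BIO12"] * f_wet
    bio["BIO19"] = bio["BIO12"] * (0.9 - f_wet).clip(0.05, 0.9)
    bioclim = {k: layer(bio[k]) for k in BIOCLIM_KEYS}

    # --- land cover: elevation/precipitation rules + categorical noise -----
    u = 0.5 * (1 + _smooth_field(rng_land, (nrow, ncol), 5)).clip(0, 2) / 2  # [0,1]-ish
    p12 = bio["BIO12"]
    lc = np.full((nrow, ncol), 7, dtype=int)                  # Bare Areas Gravel Rock
    lc[(p12 < 70) & (elev < 350) & (u < 0.55)] = 8            # Bare Areas Sand
    lc[(p12 >= 70) & (p12 < 120)] = np.where(u[(p12 >= 70) & (p12 < 120)] < 0.5, 6, 7)
    lc[(p12 >= 120) & (p12 < 190)] = np.where(u[(p12 >= 120) & (p12 < 190)] < 0.5, 4, 5)
    dense = p12 >= 190
    lc[dense] = np.select(
        [u[dense] < 0.35, u[dense] < 0.6, u[dense] < 0.8],
        [1, 3, 2], default=4,
    )
    for _ in range(max(2, n_regions // 2)):                   # a few urban patches
        r0 = rng_land.integers(0, nrow - 4)
        c0 = rng_land.integers(0, ncol - 4)
        sz = int(rng_land.integers(2, 5))
        lc[r0:r0 + sz, c0:c0 + sz] = 9
    landcover = layer(lc, kind="categorical")

    # --- boundary and regions ----------------------------------------------
    cx, cy = w + 0.5 * span_x, s + 0.5 * span_y
    boundary_geom = _blob_polygon(rng_poly, cx, cy, 0.42 * min(span_x, span_y) * 2 / 2 + 0.28 * min(span_x, span_y),
                                  irregularity=0.18, n_vertices=72)
    boundary_geom = boundary_geom.intersection(box(w + resolution, s + resolution,
                                                   e - resolution, n - resolution))
    boundary = PolygonSet([("study_area", boundary_geom, {})])

    seeds_xy = []
    while len(seeds_xy) < n_regions:
        p = Point(rng_poly.uniform(w, e), rng_poly.uniform(s, n))
        if boundary_geom.contains(p):
            seeds_xy.append(p)
    vor = voronoi_diagram(MultiPoint(seeds_xy), envelope=box(w, s, e, n))
    region_feats = []
    for i, p in enumerate(seeds_xy):
        for cellg in vor.geoms:
            if cellg.contains(p):
                clipped = cellg.intersection(boundary_geom)
                if not clipped.is_empty:
                    region_feats.append((f"region_{i + 1:02d}", clipped, {}))
                break
    regions = PolygonSet(region_feats)

    # --- protected areas: log-uniform sizes, scaled to target coverage -----
    pa_feats: list[tuple[str, shapely.Geometry, dict]] = []
    if n_protected > 0 and protected_coverage_fraction > 0:
        # radii spanning several orders of magnitude (Khawr ponds to Samhan-scale)
        log_r = rng_pa.uniform(-2.2, 0.0, size=n_protected)
        radii = (10.0 ** log_r) * 0.25 * min(span_x, span_y)
        centers = []
        while len(centers) < n_protected:
            p = Point(rng_pa.uniform(w, e), rng_pa.uniform(s, n))
            if boundary_geom.contains(p):
                centers.append(p)
        shapes = []
        scale = 1.0
        target = protected_coverage_fraction * boundary_geom.area
        for _ in range(8):  # fixed-point iteration on the union area
            shapes = [
                _blob_polygon(np.random.default_rng(np.random.SeedSequence([seed, 17, i])),
                              c.x, c.y, float(r) * scale, irregularity=0.2, n_vertices=36)
                .intersection(boundary_geom)
                for i, (c, r) in enumerate(zip(centers, radii))
            ]
            got = shapely.unary_union(shapes).area
            if got <= 0:
                scale *= 2.0
                continue
            if abs(got - target) / target < 0.02:
                break
            scale *= math.sqrt(target / got)
        pa_feats = [(f"PA_{i + 1:02d}", g, {}) for i, g in enumerate(shapes) if not g.is_empty]
    protected_areas = PolygonSet(pa_feats)

    world = SyntheticWorld(seed, extent, layer(elev), bioclim, landcover,
                           boundary, regions, protected_areas)
    _audit_invariants(world)
    return world


def _audit_invariants(world: SyntheticWorld) -> None:
    b = {k: r.values for k, r in world.bioclim.items()}
    assert np.all(b["BIO5"] >= b["BIO1"]) and np.all(b["BIO1"] >= b["BIO6"])
    assert np.all(b["BIO12"] >= b["BIO13"]) and np.all(b["BIO13"] >= 0)
    assert np.all(b["BIO12"] >= b["BIO16"] - 1e-9)
    codes = set(np.unique(world.landcover.values)) - {world.landcover.nodata}
    assert codes <= set(LANDCOVER_CLASSES)


def generate_species(
    world: SyntheticWorld,
    seed: int = 0,
    n_species: int = 30,
    records_per_species_range: tuple[int, int] = (3, 60),
    effort_bias: float = 1.0,
    prevalences: dict[str, float] | None = None,
    exhaustive: bool = False,
    suitability_threshold: float = 0.5,
    fixed_niches: pd.DataFrame | None = None,
) -> tuple[OccurrenceTable, GroundTruth]:
    """Sample niche-driven occurrences with known ground truth.

    Each species receives a Gaussian suitability surface in (BIO1, BIO12)
    space; its true range is the set of boundary pixels whose suitability
    exceeds ``suitability_threshold``.  Records are drawn from the true
    range with probability proportional to suitability × a spatially uneven
    effort surface (``effort_bias = 0`` → uniform effort).  With
    ``exhaustive=True`` every occupied pixel yields exactly one record at
    its center, so pipeline range estimates must match the truth.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    prev = dict(DEFAULT_PREVALENCES)
    if prevalences:
        prev.update(prevalences)

    streams = np.random.SeedSequence(seed).spawn(3)
    rng_niche, rng_sample, rng_attr = (np.random.default_rng(ss) for ss in streams)

    mask = world.boundary_pixel_mask()
    rows, cols = np.nonzero(mask)
    lons, lats = world.elevation.centers()
    b1 = world.bioclim["BIO1"].values[rows, cols]
    b12 = world.bioclim["BIO12"].values[rows, cols]
    res = world.resolution
    areas = pixel_area_km2(lats[rows], (res, res))

    pa_union = world.protected_areas.union()
    if not pa_union.is_empty:
        shapely.prepare(pa_union)
        in_pa = shapely.contains_xy(pa_union, lons[cols], lats[rows])
    else:
        in_pa = np.zeros(rows.shape, bool)

    effort = np.ones(rows.shape)
    if effort_bias != 0:
        z = _smooth_field(np.random.default_rng(streams[1].spawn(1)[0]),
                          world.elevation.shape, sigma=max(4, world.elevation.shape[1] // 15))
        effort = np.exp(effort_bias * z[rows, cols])

    b1_lo, b1_hi = float(b1.min()), float(b1.max())
    b12_lo, b12_hi = float(b12.min()), float(b12.max())

    archetypes = ("generalist", "montane", "desert", "mesic")
    arch_p = (0.2, 0.3, 0.3, 0.2)

    recs: list[dict] = []
    truth_rows = []
    occupied: dict[str, set[tuple[int, int]]] = {}
    aoo_true: dict[str, float] = {}
    pct_true: dict[str, float] = {}

    fixed = None
    if fixed_niches is not None:
        fixed = fixed_niches.set_index("species_id")

    for i in range(n_species):
        sp = f"sp{i + 1:03d}"
        if fixed is not None and sp in fixed.index:
            row_f = fixed.loc[sp]
            c1, w1 = float(row_f["bio1_center"]), float(row_f["bio1_width"])
            c12, w12 = float(row_f["bio12_center"]), float(row_f["bio12_width"])
            arch = "fixed"
            suit = np.exp(-0.5 * (((b1 - c1) / w1) ** 2 + ((b12 - c12) / w12) ** 2))
            occ_mask = suit >= suitability_threshold
        else:
            arch = archetypes[rng_niche.choice(len(archetypes), p=arch_p)]
            c1 = c12 = w1 = w12 = float("nan")
            suit = np.zeros_like(b1)
            occ_mask = np.zeros(b1.shape, bool)
        for attempt in range(50):
            if arch == "fixed":
                break
            if arch == "generalist":
                c1, c12 = rng_niche.uniform(b1_lo, b1_hi), rng_niche.uniform(b12_lo, b12_hi)
                w1, w12 = rng_niche.uniform(6, 12), rng_niche.uniform(250, 600)
            elif arch == "montane":
                c1 = rng_niche.uniform(b1_lo, b1_lo + 0.3 * (b1_hi - b1_lo))
                c12 = rng_niche.uniform(b12_lo + 0.4 * (b12_hi - b12_lo), b12_hi)
                w1, w12 = rng_niche.uniform(1.5, 3.5), rng_niche.uniform(40, 120)
            elif arch == "desert":
                c1 = rng_niche.uniform(b1_lo + 0.6 * (b1_hi - b1_lo), b1_hi)
                c12 = rng_niche.uniform(b12_lo, b12_lo + 0.25 * (b12_hi - b12_lo))
                w1, w12 = rng_niche.uniform(1.5, 4.0), rng_niche.uniform(25, 90)
            else:  # mesic mid-range
                c1 = rng_niche.uniform(b1_lo + 0.2 * (b1_hi - b1_lo), b1_lo + 0.7 * (b1_hi - b1_lo))
                c12 = rng_niche.uniform(b12_lo + 0.1 * (b12_hi - b12_lo), b12_lo + 0.6 * (b12_hi - b12_lo))
                w1, w12 = rng_niche.uniform(2.0, 5.0), rng_niche.uniform(40, 150)
            suit = np.exp(-0.5 * (((b1 - c1) / w1) ** 2 + ((b12 - c12) / w12) ** 2))
            occ_mask = suit >= suitability_threshold
            if occ_mask.any():
                break
            logger.warning("species %s: zero-suitability domain, resampling niche center", sp)
        occ_idx = np.nonzero(occ_mask)[0]
        pixset = {(int(rows[j]), int(cols[j])) for j in occ_idx}
        occupied[sp] = pixset
        area_occ = float(areas[occ_idx].sum())
        aoo_true[sp] = area_occ
        prot = float(areas[occ_idx][in_pa[occ_idx]].sum())
        pct_true[sp] = 100.0 * prot / area_occ if area_occ > 0 else float("nan")
        truth_rows.append({"species_id": sp, "archetype": arch,
                           "bio1_center": c1, "bio1_width": w1,
                           "bio12_center": c12, "bio12_width": w12,
                           "n_true_pixels": len(pixset)})

        if exhaustive:
            draw = occ_idx
            jit = np.zeros((len(draw), 2))
        else:
            n_rec = int(rng_sample.integers(records_per_species_range[0],
                                            records_per_species_range[1] + 1))
            p = suit[occ_idx] * effort[occ_idx]
            p = p / p.sum()
            draw = rng_sample.choice(occ_idx, size=n_rec, replace=True, p=p)
            jit = rng_sample.uniform(-0.45, 0.45, size=(len(draw), 2)) * res
        for k, j in enumerate(draw):
            recs.append({"species_id": sp,
                         "lon": float(lons[cols[j]] + jit[k, 0]),
                         "lat": float(lats[rows[j]] + jit[k, 1]),
                         "source_tag": "synthetic"})

    attr = pd.DataFrame({"species_id": [f"sp{i + 1:03d}" for i in range(n_species)]})
    for flag, p in prev.items():
        attr[flag] = rng_attr.random(n_species) < p
    iucn_keys = list(DEFAULT_IUCN_WEIGHTS)
    iucn_p = np.array(list(DEFAULT_IUCN_WEIGHTS.values()), float)
    attr["iucn"] = rng_attr.choice(iucn_keys, size=n_species, p=iucn_p / iucn_p.sum())
    grp_keys = list(DEFAULT_GROUP_WEIGHTS)
    grp_p = np.array(list(DEFAULT_GROUP_WEIGHTS.values()), float)
    attr["group"] = rng_attr.choice(grp_keys, size=n_species, p=grp_p / grp_p.sum())

    truth = GroundTruth(
        niches=pd.DataFrame(truth_rows),
        occupied=occupied,
        aoo_km2=aoo_true,
        percent_protected=pct_true,
        attributes=attr,
    )
    occ = OccurrenceTable(pd.DataFrame(recs, columns=["species_id", "lon", "lat", "source_tag"]))
    world.truth = truth
    return occ, truth
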