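"""Species range estimation (AOO and altitude-filtered MCP) and the
protected-area gap analysis.

Two range estimators per species: the area of occupancy (AOO) — occupied
pixels of the ~1 km analysis raster, optionally aggregated to 2×2 blocks
(~4 km²) — and the extent of occurrence (EOO) — all analysis pixels whose
centers fall inside the minimum convex polygon of the records and pass an
altitude filter derived from the records' elevations.  Species with fewer
than three non-collinear records fall back to their AOO-style pixel set.
Each estimate is overlaid with the protected-area polygons (a pixel is
protected iff its center lies inside any protected area) and scored against
the 17% (Aichi Target 11) and 12% protection targets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon

from .geodata_io import (
    OccurrenceTable,
    PolygonSet,
    RasterLayer,
    extract_at_points,
    pixel_area_km2,
)
from .summaries import round_half_up

logger = logging.getLogger("gapatlas")


@dataclass
class RangeEstimate:
    species_id: str
    method: Literal["AOO", "EOO"]
    resolution_km: float
    pixel_set: set[tuple[int, int]]
    area_km2: float
    protected_km2: float = 0.0
    percent_protected: float = float("nan")
    fallback_used: bool = False

    def __post_init__(self) -> None:
        if self.protected_km2 > self.area_km2 + 1e-9:
            raise ValueError("protected area cannot exceed range area")


def _occupied_pixels(occ_species: OccurrenceTable, template: RasterLayer) -> set[tuple[int, int]]:
    row, col = template.rowcol(occ_species.lon, occ_species.lat)
    nrow, ncol = template.shape
    ok = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    return set(zip(row[ok].tolist(), col[ok].tolist()))


def _pixel_area(pixels: set[tuple[int, int]], template: RasterLayer) -> float:
    if not pixels:
        return 0.0
    _, lats = template.centers()
    rows = np.array([r for r, _ in pixels])
    return float(np.sum(pixel_area_km2(lats[rows], template.resolution)))


def aoo(occ_species: OccurrenceTable, template: RasterLayer,
        resolution_km: float = 1.0) -> RangeEstimate:
    """Area of occupancy at the analysis resolution (1 km) or 2×2 blocks (4 km²).

    At 4 km² the pixel set holds block ids (row//2, col//2) and the area is
    the full footprint of each occupied block.
    """
    sp = occ_species.records["species_id"].iloc[0]
    pixels = _occupied_pixels(occ_species, template)
    if resolution_km <= 1.0:
        return RangeEstimate(sp, "AOO", 1.0, pixels, _pixel_area(pixels, template))
    blocks = {(r // 2, c // 2) for r, c in pixels}
    # block area = footprint of its four constituent analysis pixels
    nrow, ncol = template.shape
    members = {
        (2 * br + dr, 2 * bc + dc)
        for br, bc in blocks for dr in (0, 1) for dc in (0, 1)
        if 2 * br + dr < nrow and 2 * bc + dc < ncol
    }
    return RangeEstimate(sp, "AOO", 4.0, blocks, _pixel_area(members, template))


def mcp(occ_species: OccurrenceTable) -> Polygon | None:
    """Minimum convex polygon of the records, or None as the fallback signal
    when fewer than three non-collinear points exist."""
    pts = MultiPoint(list({(x, y) for x, y in zip(occ_species.lon, occ_species.lat)}))
    hull = pts.convex_hull
    if isinstance(hull, Polygon) and hull.area > 0:
        return hull
    return None


def eoo(
    occ_species: OccurrenceTable,
    mcp_polygon: Polygon | None,
    elevation: RasterLayer,
    template: RasterLayer | None = None,
    filter_mode: Literal["observed-range", "mean-band"] = "observed-range",
    k_sd: float = 1.0,
) -> RangeEstimate:
    """Extent of occurrence: analysis pixels inside the MCP passing the
    altitude filter, plus the occupied (AOO) pixels themselves.

    ``observed-range`` keeps pixels whose elevation lies within the [min,
    max] of the records' elevations (the default; it guarantees
    AOO ⊆ EOO).  ``mean-band`` keeps pixels within mean ± k_sd·sd.  With no
    valid MCP the estimate falls back to the AOO-style pixel set.
    """
    sp = occ_species.records["species_id"].iloc[0]
    template = template if template is not None else elevation
    occupied = _occupied_pixels(occ_species, template)
    if mcp_polygon is None:
        return RangeEstimate(sp, "EOO", 1.0, occupied,
                             _pixel_area(occupied, template), fallback_used=True)

    elev = extract_at_points(elevation, occ_species)
    ev = elev.loc[elev["valid"], "value"].to_numpy(float)
    lons, lats = template.centers()
    gx, gy = np.meshgrid(lons, lats)
    shapely.prepare(mcp_polygon)
    inside = shapely.contains_xy(mcp_polygon, gx.ravel(), gy.ravel()).reshape(gx.shape)
    # resample elevation onto the template grid if the grids differ
    if elevation.shape == template.shape and elevation.origin == template.origin:
        ez = elevation.values
        evalid = elevation.mask_valid()
    else:
        r, c = elevation.rowcol(gx.ravel(), gy.ravel())
        r = np.clip(r, 0, elevation.shape[0] - 1)
        c = np.clip(c, 0, elevation.shape[1] - 1)
        ez = elevation.values[r, c].reshape(gx.shape)
        evalid = elevation.mask_valid()[r, c].reshape(gx.shape)
    if len(ev) == 0:
        passes = np.ones_like(inside)
    elif filter_mode == "observed-range":
        passes = (ez >= ev.min()) & (ez <= ev.max())
    elif filter_mode == "mean-band":
        mu, sd = float(ev.mean()), float(ev.std(ddof=0))
        passes = (ez >= mu - k_sd * sd) & (ez <= mu + k_sd * sd)
    else:
        raise ValueError(f"unknown filter_mode {filter_mode!r}")
    rows, cols = np.nonzero(inside & passes & evalid)
    pixels = set(zip(rows.tolist(), cols.tolist())) | occupied
    return RangeEstimate(sp, "EOO", 1.0, pixels, _pixel_area(pixels, template))


def protected_fraction(estimate: RangeEstimate, pas: PolygonSet,
                       template: RasterLayer) -> RangeEstimate:
    """Overlay a range estimate with the protected-area polygons.

    A pixel (or 4 km² block) counts as protected iff its center lies inside
    any protected-area polygon; the percentage is rounded half-up to 2 dp.
    An empty range leaves the percentage undefined (NaN) and is flagged in
    downstream tables.
    """
    if not estimate.pixel_set:
        estimate.protected_km2 = 0.0
        estimate.percent_protected = float("nan")
        return estimate
    lons, lats = template.centers()
    if estimate.resolution_km > 1.0:
        # block centers: mean of the (up to) four member pixel centers
        nrow, ncol = template.shape
        cx, cy, areas = [], [], []
        for br, bc in estimate.pixel_set:
            rr = [2 * br + d for d in (0, 1) if 2 * br + d < nrow]
            cc = [2 * bc + d for d in (0, 1) if 2 * bc + d < ncol]
            cx.append(np.mean([lons[c] for c in cc]))
            cy.append(np.mean([lats[r] for r in rr]))
            areas.append(sum(pixel_area_km2(lats[r], template.resolution)
                             for r in rr for _ in cc))
        cx, cy, areas = np.array(cx), np.array(cy), np.array(areas)
    else:
        rows = np.array([r for r, _ in estimate.pixel_set])
        cols = np.array([c for _, c in estimate.pixel_set])
        cx, cy = lons[cols], lats[rows]
        areas = pixel_area_km2(lats[rows], template.resolution)
    union = pas.union()
    if union.is_empty:
        inside = np.zeros(len(cx), bool)
    else:
        shapely.prepare(union)
        inside = shapely.contains_xy(union, cx, cy)
    estimate.protected_km2 = float(areas[inside].sum())
    estimate.percent_protected = round_half_up(
        100.0 * estimate.protected_km2 / estimate.area_km2, 2
    )
    return estimate


@dataclass
class ProtectionSummary:
    table: pd.DataFrame                    # one row per species × method
    counts: dict[str, dict] = field(default_factory=dict)

    def bar_data(self, method: str) -> pd.DataFrame:
        sub = self.table[self.table["method"] == method]
        return sub.sort_values(["percent_protected", "species_id"],
                               ascending=[False, True], kind="mergesort").reset_index(drop=True)


def species_range_table(
    occ: OccurrenceTable,
    elevation: RasterLayer,
    pas: PolygonSet,
    template: RasterLayer | None = None,
    filter_mode: Literal["observed-range", "mean-band"] = "observed-range",
) -> list[RangeEstimate]:
    """Both range estimators with protection overlay for every species."""
    template = template if template is not None else elevation
    out = []
    for sp in occ.species:
        sub = occ.subset(sp)
        est_aoo = protected_fraction(aoo(sub, template, 1.0), pas, template)
        est_eoo = protected_fraction(
            eoo(sub, mcp(sub), elevation, template, filter_mode), pas, template
        )
        out.extend([est_aoo, est_eoo])
    return out


def gap_report(
    estimates: list[RangeEstimate],
    attributes: pd.DataFrame,
    targets: tuple[float, ...] = (17.0, 12.0),
) -> ProtectionSummary:
    """Score all species against the protection targets.

    Produces the per-species table (both approaches) and the headline
    counts: species above each target per approach, combined counts (a
    species passes combined if it passes under either approach), species
    with zero protection, and endemic-only breakdowns.
    """
    attr = attributes.set_index("species_id") if "species_id" in attributes.columns else attributes
    rows = []
    for est in estimates:
        rows.append({
            "species_id": est.species_id,
            "method": est.method,
            "endemic": bool(attr.loc[est.species_id, "endemic"]) if est.species_id in attr.index else False,
            "area_km2": est.area_km2,
            "protected_km2": est.protected_km2,
            "percent_protected": est.percent_protected,
            "fallback_used": est.fallback_used,
            "empty_range": len(est.pixel_set) == 0,
        })
    table = pd.DataFrame(rows).sort_values(["species_id", "method"], kind="mergesort").reset_index(drop=True)

    counts: dict[str, dict] = {}
    methods = sorted(table["method"].unique())
    for t in targets:
        per_method = {}
        passing_union: set[str] = set()
        passing_union_end: set[str] = set()
        for m in methods:
            sub = table[table["method"] == m]
            passed = sub.loc[sub["percent_protected"] >= t, "species_id"]
            per_method[m] = int(len(passed))
            per_method[f"{m}_endemic"] = int(sub.loc[
                (sub["percent_protected"] >= t) & sub["endemic"], "species_id"
            ].size)
            passing_union |= set(passed)
            passing_union_end |= set(sub.loc[
                (sub["percent_protected"] >= t) & sub["endemic"], "species_id"
            ])
        per_method["combined"] = len(passing_union)
        per_method["combined_endemic"] = len(passing_union_end)
        counts[f"target_{t:g}"] = per_method
    zero = {}
    for m in methods:
        sub = table[table["method"] == m]
        z = sub["percent_protected"].fillna(0.0) == 0.0
        zero[m] = int(z.sum())
        zero[f"{m}_endemic"] = int((z & sub["endemic"]).sum())
    counts["zero_protection"] = zero
    return ProtectionSummary(table=table, counts=counts)
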