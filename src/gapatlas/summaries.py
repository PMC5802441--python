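"""Richness, endemicity and tally arithmetic.

Houses the distinct-species counts per grid cell / region / protected area,
sampling-effort coverage, IUCN category tallies, and the half-up percentage
rounding used in every printed table.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import shapely

from .geodata_io import (
    IUCN_CATEGORIES,
    GridSystem,
    OccurrenceTable,
    PolygonSet,
    RasterLayer,
    spatial_join,
)

logger = logging.getLogger("gapatlas")


def round_half_up(x: float, dp: int = 2) -> float:
    """Round half away from zero at ``dp`` decimals (table formatting rule)."""
    if not np.isfinite(x):
        return float("nan")
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int, dp: int = 2) -> float:
    """100·n/d rounded half-up to ``dp`` decimals; undefined for d = 0."""
    if denominator == 0:
        raise ZeroDivisionError("percent undefined for zero denominator")
    return round_half_up(100.0 * numerator / denominator, dp)


def _species_by_region(occ: OccurrenceTable, polys: PolygonSet) -> dict[str, set[str]]:
    """Species per polygon, record assigned to the first containing feature
    in file order (boundary-touching records logged)."""
    prepared = []
    for name, geom, _ in polys.features:
        shapely.prepare(geom)
        prepared.append((name, geom))
    out: dict[str, set[str]] = {name: set() for name, _ in prepared}
    lon, lat = occ.lon, occ.lat
    species = occ.records["species_id"].to_numpy()
    claimed = np.zeros(len(lon), bool)
    for name, geom in prepared:
        hit = shapely.intersects_xy(geom, lon, lat)
        new = hit & ~claimed
        ties = hit & claimed
        if ties.any():
            logger.info("richness: %d boundary record(s) already assigned before %s",
                        int(ties.sum()), name)
        for sp in set(species[new]):
            out[name].add(sp)
        claimed |= hit
    return out


def richness(
    occ: OccurrenceTable,
    units: GridSystem | PolygonSet,
    attributes: pd.DataFrame | None = None,
    filter: str | None = None,
) -> pd.DataFrame:
    """Distinct species with ≥1 record per unit, optionally restricted to an
    attribute subset (e.g. ``filter="endemic"``)."""
    keep: set[str] | None = None
    if filter is not None:
        if attributes is None or filter not in attributes.columns:
            raise ValueError(f"attribute filter {filter!r} needs an attribute table with that column")
        keep = set(attributes.loc[attributes[filter].astype(bool), "species_id"])

    if isinstance(units, GridSystem):
        joined = spatial_join(occ, units)
        per_cell: dict[tuple[int, int], set[str]] = {}
        for sp, cells in joined.items():
            if sp == "__all__" or (keep is not None and sp not in keep):
                continue
            for cell in cells:
                per_cell.setdefault(cell, set()).add(sp)
        rows = [{"unit": f"{c}:{r}", "col": c, "row": r, "richness": len(sps)}
                for (c, r), sps in sorted(per_cell.items())]
        return pd.DataFrame(rows, columns=["unit", "col", "row", "richness"])

    by_region = _species_by_region(occ, units)
    rows = []
    for name, _, _ in units.features:
        sps = by_region[name]
        if keep is not None:
            sps = sps & keep
        rows.append({"unit": name, "richness": len(sps)})
    return pd.DataFrame(rows, columns=["unit", "richness"])


def richness_raster(occ: OccurrenceTable, grid: GridSystem,
                    attributes: pd.DataFrame | None = None,
                    filter: str | None = None) -> RasterLayer:
    """Per-cell richness as a coarse raster on the analysis graticule."""
    table = richness(occ, grid, attributes, filter)
    vals = np.zeros((grid.nrows, grid.ncols), dtype=int)
    for _, rec in table.iterrows():
        vals[grid.nrows - 1 - int(rec["row"]), int(rec["col"])] = int(rec["richness"])
    w, s, e, n = grid.extent
    return RasterLayer(vals, (w, n), (grid.cell_size_deg, grid.cell_size_deg),
                       nodata=-1, kind="categorical")


def pa_representation(occ: OccurrenceTable, attributes: pd.DataFrame,
                      pas: PolygonSet, dp: int = 2) -> pd.DataFrame:
    """Which species have at least one record inside a protected area.

    Returns counts and percentages overall and for each boolean attribute
    subset (endemic, venomous, ...).
    """
    all_species = set(occ.species)
    if len(pas) == 0:
        inside_species: set[str] = set()
    else:
        union = pas.union()
        shapely.prepare(union)
        hit = shapely.intersects_xy(union, occ.lon, occ.lat)
        inside_species = set(occ.records["species_id"].to_numpy()[hit])

    rows = [{"subset": "all", "n_total": len(all_species),
             "n_represented": len(inside_species & all_species),
             "percent": percent(len(inside_species & all_species), len(all_species), dp)
             if all_species else float("nan")}]
    for colname in ("endemic", "venomous", "island"):
        if colname not in attributes.columns:
            continue
        subset = set(attributes.loc[attributes[colname].astype(bool), "species_id"]) & all_species
        n_rep = len(subset & inside_species)
        rows.append({"subset": colname, "n_total": len(subset), "n_represented": n_rep,
                     "percent": percent(n_rep, len(subset), dp) if subset else float("nan")})
    if "iucn" in attributes.columns:
        threatened = set(attributes.loc[attributes["iucn"].isin(["VU", "NT"]),
                                        "species_id"]) & all_species
        n_rep = len(threatened & inside_species)
        rows.append({"subset": "threatened", "n_total": len(threatened), "n_represented": n_rep,
                     "percent": percent(n_rep, len(threatened), dp) if threatened else float("nan")})
    return pd.DataFrame(rows)


def sampling_coverage(occ: OccurrenceTable, grid: GridSystem, dp: int = 2) -> dict:
    """Sampled vs total study cells and the sampling percentage."""
    joined = spatial_join(occ, grid)
    sampled = joined["__all__"] & grid.study_mask
    total = len(grid.study_mask)
    return {
        "cells_sampled": len(sampled),
        "cells_total": total,
        "percent_sampled": percent(len(sampled), total, dp) if total else float("nan"),
    }


def iucn_tally(attributes: pd.DataFrame, by: str | None = None) -> pd.DataFrame:
    """Counts per IUCN category (LC and LC* reported separately).

    With ``by`` set to a column name, tallies are produced per group of that
    column; unknown category codes raise.
    """
    cats = attributes["iucn"]
    bad = set(cats.dropna()) - set(IUCN_CATEGORIES)
    if bad:
        raise ValueError(f"unknown IUCN categories: {sorted(bad)}")
    if by is None:
        counts = cats.value_counts()
        return pd.DataFrame([{**{c: int(counts.get(c, 0)) for c in IUCN_CATEGORIES},
                              "total": int(len(attributes))}])
    rows = []
    for key, sub in attributes.groupby(by):
        counts = sub["iucn"].value_counts()
        rows.append({by: key, **{c: int(counts.get(c, 0)) for c in IUCN_CATEGORIES},
                     "total": int(len(sub))})
    return pd.DataFrame(rows)
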