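"""Spatial input/output, the analysis graticule, and coordinate/area conventions.

All coordinates are geographic (longitude/latitude, WGS84, decimal degrees).
Rasters are plain-text Esri ASCII grids with square cells; vector layers are
GeoJSON; occurrence tables and summaries are CSV.  Grid cells and raster
pixels use half-open intervals: a point on a shared west/south edge belongs
to the cell to its east/north-east — i.e. [west, east) × [south, north).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import box, mapping, shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger("gapatlas")

#: kilometres per degree of latitude (spherical approximation)
KM_PER_DEGREE = 111.32

IUCN_CATEGORIES = ("NE", "DD", "LC", "LC*", "NT", "VU")
TAXON_GROUPS = ("gecko", "snake", "agamid", "skink", "lacertid", "varanid", "amphisbaenid")

#: land-cover class codes and names used throughout the pipeline
LANDCOVER_CLASSES = {
    1: "Tree Open",
    2: "Cropland",
    3: "Cropland / Other vegetation mosaic",
    4: "Shrub",
    5: "Herbaceous",
    6: "Sparse Vegetation",
    7: "Bare Areas Gravel Rock",
    8: "Bare Areas Sand",
    9: "Urban",
}


class FormatError(ValueError):
    """A file does not satisfy the expected tabular/vector/raster contract."""


class EmptyTableError(FormatError):
    """An input table holds no usable records."""


# ---------------------------------------------------------------------------
# Occurrence tables
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceTable:
    """Point records of species observations.

    ``records`` is a DataFrame with columns ``species_id``, ``lon``, ``lat``
    and optionally ``source_tag``.  Duplicate (species, lon, lat) rows are
    retained on input; deduplication to occupied pixels/cells happens in the
    downstream operations that need it.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"species_id", "lon", "lat"}
        missing = required - set(self.records.columns)
        if missing:
            raise FormatError(f"occurrence table missing columns: {sorted(missing)}")
        r = self.records
        bad = (
            (r["lon"] < -180) | (r["lon"] > 180)
            | (r["lat"] < -90) | (r["lat"] > 90)
            | r["species_id"].astype(str).str.len().eq(0)
        )
        if bad.any():
            raise ValueError(f"{int(bad.sum())} records violate coordinate/species invariants")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species_id"].unique())

    def subset(self, species_id: str) -> "OccurrenceTable":
        return OccurrenceTable(self.records[self.records["species_id"] == species_id].reset_index(drop=True))

    @property
    def lon(self) -> np.ndarray:
        return self.records["lon"].to_numpy(float)

    @property
    def lat(self) -> np.ndarray:
        return self.records["lat"].to_numpy(float)


def read_occurrences(
    path: str | Path,
    format: Literal["delimited-table", "vector-points"] = "delimited-table",
    species_col: str = "species_id",
    lon_col: str = "lon",
    lat_col: str = "lat",
) -> OccurrenceTable:
    """Read occurrence records from a delimited table or a GeoJSON point file.

    Rows with unparseable or out-of-range coordinates are dropped and
    counted in the log; an entirely empty file raises ``EmptyTableError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited-table":
        df = pd.read_csv(path)
        for col in (species_col, lon_col, lat_col):
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r} in {path.name}")
        df = df.rename(columns={species_col: "species_id", lon_col: "lon", lat_col: "lat"})
    elif format == "vector-points":
        with open(path) as fh:
            gj = json.load(fh)
        rows = []
        for feat in gj.get("features", []):
            geom = feat.get("geometry") or {}
            props = feat.get("properties") or {}
            if geom.get("type") != "Point":
                continue
            x, y = geom["coordinates"][:2]
            rows.append({"species_id": props.get(species_col, props.get("species_id")),
                        "lon": x, "lat": y,
                        "source_tag": props.get("source_tag", "")})
        df = pd.DataFrame(rows, columns=["species_id", "lon", "lat", "source_tag"])
    else:
        raise ValueError(f"unknown format {format!r}")

    if df.empty:
        raise EmptyTableError(f"{path.name} holds no records")

    n0 = len(df)
    df["lon"] = pd.to_numeric(df["lon"], errors="coerce")
    df["lat"] = pd.to_numeric(df["lat"], errors="coerce")
    ok = (
        df["lon"].between(-180, 180) & df["lat"].between(-90, 90)
        & df["species_id"].notna() & df["species_id"].astype(str).str.len().gt(0)
    )
    dropped = n0 - int(ok.sum())
    if dropped:
        logger.warning("read_occurrences: dropped %d record(s) with invalid coordinates", dropped)
    df = df[ok].reset_index(drop=True)
    if df.empty:
        raise EmptyTableError(f"{path.name}: all {n0} records invalid")
    if "source_tag" not in df.columns:
        df["source_tag"] = ""
    return OccurrenceTable(df[["species_id", "lon", "lat", "source_tag"]])


def write_occurrences(occ: OccurrenceTable, path: str | Path) -> None:
    df = occ.records.sort_values(["species_id", "lon", "lat"], kind="mergesort")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Species attributes
# ---------------------------------------------------------------------------

def read_species_attributes(path: str | Path) -> pd.DataFrame:
    """Species attribute table: endemic/venomous/island/described flags,
    IUCN category (closed vocabulary) and taxonomic group."""
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise FormatError("attribute table needs a species_id column")
    bad = set(df.get("iucn", pd.Series(dtype=str)).dropna()) - set(IUCN_CATEGORIES)
    if bad:
        raise FormatError(f"unknown IUCN categories: {sorted(bad)}")
    for flag in ("endemic", "venomous", "island", "described"):
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Rasters
# ---------------------------------------------------------------------------

@dataclass
class RasterLayer:
    """Georeferenced gridded surface on a regular lon/lat lattice.

    ``origin`` is the (west, north) corner of the top-left pixel; pixel (0,0)
    is the north-west pixel, rows run southward (the ASCII-grid convention).
    """

    values: np.ndarray
    origin: tuple[float, float]          # (west, north)
    resolution: tuple[float, float]      # (d_lon, d_lat), both > 0
    nodata: float = -9999.0
    kind: Literal["continuous", "categorical"] = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.resolution[0] <= 0 or self.resolution[1] <= 0:
            raise ValueError("resolution components must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(west, south, east, north)."""
        nrow, ncol = self.values.shape
        w, n = self.origin
        return (w, n - nrow * self.resolution[1], w + ncol * self.resolution[0], n)

    def rowcol(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pixel indices containing the given points (half-open pixels)."""
        w, n = self.origin
        col = np.floor((np.asarray(lon, float) - w) / self.resolution[0]).astype(int)
        row = np.floor((n - np.asarray(lat, float)) / self.resolution[1]).astype(int)
        # north/west edges are inclusive at the raster border
        nrow, ncol = self.values.shape
        row = np.where((np.asarray(lat, float) == n), 0, row)
        return row, col

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Longitude and latitude of every pixel center (1-D each)."""
        nrow, ncol = self.values.shape
        w, n = self.origin
        lons = w + (np.arange(ncol) + 0.5) * self.resolution[0]
        lats = n - (np.arange(nrow) + 0.5) * self.resolution[1]
        return lons, lats

    def mask_valid(self) -> np.ndarray:
        if np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata


def read_raster(path: str | Path, kind: Literal["continuous", "categorical"] = "continuous") -> RasterLayer:
    """Read an Esri ASCII grid (square cells, plain text)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise FormatError(f"{path.name}: missing ASCII-grid header field {key}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise FormatError(f"{path.name}: value block {values.shape} != header ({nrows},{ncols})")
    cell = header["cellsize"]
    nodata = header.get("nodata_value", -9999.0)
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    if kind == "categorical":
        values = values.astype(int)
        nodata = int(nodata)
    return RasterLayer(values, origin, (cell, cell), nodata=nodata, kind=kind)


def write_raster(raster: RasterLayer, path: str | Path) -> None:
    if abs(raster.resolution[0] - raster.resolution[1]) > 1e-12:
        raise ValueError("ASCII grids require square cells")
    nrow, ncol = raster.shape
    w, n = raster.origin
    cell = raster.resolution[0]
    header = (
        f"ncols {ncol}\nnrows {nrow}\n"
        f"xllcorner {w!r}\nyllcorner {n - nrow * cell!r}\n"
        f"cellsize {cell!r}\nnodata_value {raster.nodata!r}\n"
    )
    fmt = "%d" if raster.kind == "categorical" else "%.8g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt=fmt)


# ---------------------------------------------------------------------------
# Polygon sets
# ---------------------------------------------------------------------------

@dataclass
class PolygonSet:
    """Named polygon features (study boundary, regions, protected areas)."""

    features: list[tuple[str, BaseGeometry, dict]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [n for n, _, _ in self.features]
        if len(names) != len(set(names)):
            raise ValueError("feature names must be unique within a set")
        repaired = []
        for name, geom, attrs in self.features:
            if not geom.is_valid:
                geom = shapely.make_valid(geom)
            repaired.append((name, geom, attrs))
        self.features = repaired

    def __len__(self) -> int:
        return len(self.features)

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.features]

    def union(self) -> BaseGeometry:
        return shapely.unary_union([g for _, g, _ in self.features])

    def total_area_km2(self) -> float:
        """Union area in km² (cos-latitude spherical approximation)."""
        return geodesic_area_km2(self.union())


def geodesic_area_km2(geom: BaseGeometry) -> float:
    """Approximate area of a lon/lat geometry in km².

    Uses the spherical cos-latitude correction evaluated on thin latitude
    slabs; deterministic and accurate to well under 1% at subtropical
    latitudes.
    """
    if geom.is_empty:
        return 0.0
    miny, maxy = geom.bounds[1], geom.bounds[3]
    n = max(8, int(math.ceil((maxy - miny) / 0.05)))
    edges = np.linspace(miny, maxy, n + 1)
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        slab = geom.intersection(box(-360, lo, 360, hi))
        if slab.is_empty:
            continue
        midlat = 0.5 * (lo + hi)
        total += slab.area * KM_PER_DEGREE**2 * math.cos(math.radians(midlat))
    return total


def read_polygons(path: str | Path) -> PolygonSet:
    """Read a GeoJSON FeatureCollection of (multi)polygons."""
    with open(path) as fh:
        gj = json.load(fh)
    feats = []
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        name = str(props.get("name", f"feature_{i}"))
        geom = shape(feat["geometry"])
        feats.append((name, geom, {k: v for k, v in props.items() if k != "name"}))
    return PolygonSet(feats)


def write_polygons(polys: PolygonSet, path: str | Path) -> None:
    features = [
        {"type": "Feature",
         "properties": {"name": name, **attrs},
         "geometry": mapping(geom)}
        for name, geom, attrs in polys.features
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Analysis grid
# ---------------------------------------------------------------------------

@dataclass
class GridSystem:
    """The coarse analysis graticule (default 10 arc-minutes).

    Cells are identified by (col, row) counted eastward/northward from the
    grid's west/south edge, which is snapped to multiples of the cell size
    from the (0°, 0°) graticule origin.  Cell intervals are half-open:
    [west, east) × [south, north).
    """

    extent: tuple[float, float, float, float]   # (west, south, east, north)
    cell_size_deg: float
    study_mask: set[tuple[int, int]]

    @property
    def ncols(self) -> int:
        w, s, e, n = self.extent
        return int(round((e - w) / self.cell_size_deg))

    @property
    def nrows(self) -> int:
        w, s, e, n = self.extent
        return int(round((n - s) / self.cell_size_deg))

    @property
    def cells(self) -> list[tuple[int, int]]:
        return [(c, r) for r in range(self.nrows) for c in range(self.ncols)]

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Grid cell containing the point, or None if outside the extent."""
        w, s, e, n = self.extent
        if not (w <= lon < e and s <= lat < n):
            return None
        col = int(math.floor((lon - w) / self.cell_size_deg))
        row = int(math.floor((lat - s) / self.cell_size_deg))
        return (col, row)

    def cell_bounds(self, cell: tuple[int, int]) -> tuple[float, float, float, float]:
        w, s, _, _ = self.extent
        col, row = cell
        cw = w + col * self.cell_size_deg
        cs = s + row * self.cell_size_deg
        return (cw, cs, cw + self.cell_size_deg, cs + self.cell_size_deg)

    def cell_polygon(self, cell: tuple[int, int]) -> BaseGeometry:
        return box(*self.cell_bounds(cell))


def build_grid(study_polygon: PolygonSet, cell_size_arcmin: float = 10.0) -> GridSystem:
    """Build the analysis graticule over a study-area polygon.

    The grid covers the polygon's bounding box snapped outward to multiples
    of the cell size from the (0°, 0°) graticule origin; ``study_mask``
    holds the cells whose rectangle intersects the polygon.
    """
    if cell_size_arcmin <= 0:
        raise ValueError("cell size must be positive")
    geom = study_polygon.union()
    if geom.is_empty or geom.area == 0:
        raise ValueError("degenerate (zero-area) study polygon")
    cs = cell_size_arcmin / 60.0
    minx, miny, maxx, maxy = geom.bounds
    w = math.floor(minx / cs) * cs
    s = math.floor(miny / cs) * cs
    e = math.ceil(maxx / cs) * cs
    n = math.ceil(maxy / cs) * cs
    grid = GridSystem((w, s, e, n), cs, study_mask=set())
    prepared = shapely.prepared.prep(geom)
    mask = set()
    for cell in grid.cells:
        if prepared.intersects(grid.cell_polygon(cell)):
            mask.add(cell)
    grid.study_mask = mask
    return grid


def spatial_join(occ: OccurrenceTable, grid: GridSystem) -> dict[str, set[tuple[int, int]]]:
    """Per-species sets of occupied grid cells.

    Points outside the grid extent are logged and excluded.  The union of
    all per-species sets (the sampled-cell set) is returned under the key
    ``"__all__"``.
    """
    out: dict[str, set[tuple[int, int]]] = {}
    sampled: set[tuple[int, int]] = set()
    n_out = 0
    for sp, lon, lat in zip(occ.records["species_id"], occ.records["lon"], occ.records["lat"]):
        cell = grid.cell_of(float(lon), float(lat))
        if cell is None:
            n_out += 1
            continue
        out.setdefault(str(sp), set()).add(cell)
        sampled.add(cell)
    if n_out:
        logger.warning("spatial_join: excluded %d record(s) outside grid extent", n_out)
    out["__all__"] = sampled
    return out


# ---------------------------------------------------------------------------
# Areas and point extraction
# ---------------------------------------------------------------------------

def pixel_area_km2(lat: float | np.ndarray, resolution: tuple[float, float]) -> float | np.ndarray:
    """Area of a lon/lat pixel (d_lon × d_lat degrees) centered at ``lat``.

    Spherical approximation: one degree of latitude = 111.32 km, one degree
    of longitude = 111.32·cos(lat) km.
    """
    d_lon, d_lat = resolution
    lat = np.asarray(lat, float)
    if np.any(np.abs(lat) >= 90):
        raise ValueError("pixel center latitude must satisfy |lat| < 90")
    area = (d_lat * KM_PER_DEGREE) * (d_lon * KM_PER_DEGREE * np.cos(np.radians(lat)))
    return float(area) if area.ndim == 0 else area


def extract_at_points(raster: RasterLayer, points: OccurrenceTable) -> pd.DataFrame:
    """Value of the pixel containing each record.

    Returns a DataFrame aligned with ``points.records`` with columns
    ``value`` and ``valid`` (False for out-of-extent or nodata pixels, which
    downstream profiles exclude).  Raises if every point is outside the
    raster extent.
    """
    lon, lat = points.lon, points.lat
    w, s, e, n = raster.extent
    inside = (lon >= w) & (lon < e) & (lat > s) & (lat <= n)
    if not inside.any():
        raise ValueError("all points fall outside the raster extent")
    row, col = raster.rowcol(lon, lat)
    nrow, ncol = raster.shape
    row_c = np.clip(row, 0, nrow - 1)
    col_c = np.clip(col, 0, ncol - 1)
    vals = raster.values[row_c, col_c].astype(float)
    if np.isnan(raster.nodata):
        valid = inside & ~np.isnan(vals)
    else:
        valid = inside & (vals != raster.nodata)
    vals = np.where(inside, vals, np.nan)
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("extract_at_points: %d record(s) flagged (outside extent or nodata)", n_bad)
    return pd.DataFrame({"value": vals, "valid": valid}, index=points.records.index)


# ---------------------------------------------------------------------------
# Output bundle
# ---------------------------------------------------------------------------

def write_species_grid(species_id: str, cells: Iterable[tuple[int, int]],
                       grid: GridSystem, path: str | Path) -> None:
    """One species' occupied cells as a polygon vector file."""
    feats = [
        (f"{species_id}:{c}:{r}", grid.cell_polygon((c, r)), {"species": species_id, "col": c, "row": r})
        for c, r in sorted(cells)
    ]
    write_polygons(PolygonSet(feats), path)


def read_species_grid(path: str | Path) -> set[tuple[int, int]]:
    polys = read_polygons(path)
    return {(int(attrs["col"]), int(attrs["row"])) for _, _, attrs in polys.features}


def write_table(df: pd.DataFrame, path: str | Path, sort_by: Sequence[str] | None = None) -> None:
    """Deterministic CSV: fixed column order, stable row sort, '.' decimal."""
    out = df.copy()
    if sort_by:
        out = out.sort_values(list(sort_by), kind="mergesort")
    out.to_csv(path, index=False)
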