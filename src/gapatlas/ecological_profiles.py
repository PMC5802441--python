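"""Per-species habitat characterization.

Three views of a species' ecology, each driven directly by its occurrence
records: an elevation frequency histogram (100 m bins), the position of the
records in the two-dimensional climate space spanned by mean annual
temperature (BIO1) and total annual precipitation (BIO12), and the
distribution of distances from each record to the nearest pixel of each of
the nine land-cover classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .geodata_io import (
    KM_PER_DEGREE,
    LANDCOVER_CLASSES,
    OccurrenceTable,
    RasterLayer,
    extract_at_points,
)

logger = logging.getLogger("gapatlas")


@dataclass
class ElevationHistogram:
    species_id: str
    bin_edges: np.ndarray      # ascending; [0,100), [100,200), ...
    counts: np.ndarray
    n_valid: int
    n_dropped: int


def elevation_histogram(occ_species: OccurrenceTable, elevation: RasterLayer,
                        bin_width: float = 100.0) -> ElevationHistogram:
    """Frequency of a species' records per elevation band.

    Bins are half-open [k·w, (k+1)·w); a record at exactly a bin edge falls
    in the upper bin.  Negative elevations are folded into a single
    [min, 0) bin.  Records on nodata pixels are dropped (counted).
    """
    sp = occ_species.records["species_id"].iloc[0] if len(occ_species) else ""
    ext = extract_at_points(elevation, occ_species)
    vals = ext.loc[ext["valid"], "value"].to_numpy(float)
    n_dropped = int((~ext["valid"]).sum())
    if len(vals) == 0:
        logger.warning("elevation_histogram(%s): no records with valid elevation", sp)
        return ElevationHistogram(sp, np.array([0.0, bin_width]), np.array([0]), 0, n_dropped)
    top = np.floor(vals.max() / bin_width) * bin_width + bin_width
    edges = np.arange(0.0, top + 0.5 * bin_width, bin_width)
    if (vals < 0).any():
        edges = np.concatenate([[float(vals.min())], edges])
    # np.histogram closes the last bin on the right; pad one empty bin so
    # every populated bin stays half-open
    edges_h = np.concatenate([edges, [edges[-1] + bin_width]])
    counts, _ = np.histogram(vals, bins=edges_h)
    return ElevationHistogram(sp, edges_h, counts, len(vals), n_dropped)


def climate_envelope(
    occ_species: OccurrenceTable,
    bio1: RasterLayer,
    bio12: RasterLayer,
    background_mask: np.ndarray | None = None,
) -> dict:
    """Records plotted in (BIO1, BIO12) space, plus the background cloud.

    Returns per-record climate pairs, quantile summaries per axis, and the
    background pixel cloud (the study area's whole climate space) for
    scatter plots.
    """
    e1 = extract_at_points(bio1, occ_species)
    e12 = extract_at_points(bio12, occ_species)
    valid = e1["valid"] & e12["valid"]
    pts = pd.DataFrame({
        "BIO1": e1.loc[valid, "value"],
        "BIO12": e12.loc[valid, "value"],
    }).reset_index(drop=True)

    def summary(x: pd.Series) -> dict:
        if x.empty:
            return {q: float("nan") for q in ("min", "q25", "median", "q75", "max")}
        return {"min": float(x.min()), "q25": float(x.quantile(0.25)),
                "median": float(x.median()), "q75": float(x.quantile(0.75)),
                "max": float(x.max())}

    background = None
    if background_mask is not None:
        rows, cols = np.nonzero(background_mask)
        background = pd.DataFrame({
            "BIO1": bio1.values[rows, cols],
            "BIO12": bio12.values[rows, cols],
        })
    return {
        "climate_points": pts,
        "climate_summary": {"BIO1": summary(pts["BIO1"]), "BIO12": summary(pts["BIO12"])},
        "background": background,
        "n_excluded": int((~valid).sum()),
    }


def _equidistant_sampling(landcover: RasterLayer) -> tuple[float, float]:
    """Pixel size (km) in a world equidistant cylindrical projection with
    standard parallel 0°: x = lon·111.32 km, y = lat·111.32 km."""
    d_lon, d_lat = landcover.resolution
    return d_lat * KM_PER_DEGREE, d_lon * KM_PER_DEGREE


def class_distance_rasters(landcover: RasterLayer) -> dict[int, np.ndarray]:
    """Distance (km) from every pixel center to the nearest pixel of each
    land-cover class, via a Euclidean distance transform in the equidistant
    cylindrical projection.  Absent classes are omitted."""
    dy_km, dx_km = _equidistant_sampling(landcover)
    out = {}
    for code in LANDCOVER_CLASSES:
        present = landcover.values == code
        if not present.any():
            continue
        out[code] = distance_transform_edt(~present, sampling=(dy_km, dx_km))
    return out


def landcover_distances(occ_species: OccurrenceTable, landcover: RasterLayer,
                        distance_rasters: dict[int, np.ndarray] | None = None) -> pd.DataFrame:
    """Five-number summary of record-to-class distances per land-cover class.

    Distances are center-to-center at the raster's resolution; a record
    sitting on a pixel of class c has distance 0 to c.  Classes absent from
    the raster are reported with n = 0 and NaN statistics.
    """
    if distance_rasters is None:
        distance_rasters = class_distance_rasters(landcover)
    row, col = landcover.rowcol(occ_species.lon, occ_species.lat)
    nrow, ncol = landcover.shape
    inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    row, col = row[inside], col[inside]
    rows_out = []
    for code, name in LANDCOVER_CLASSES.items():
        if code not in distance_rasters:
            rows_out.append({"class_code": code, "class_name": name, "n": 0,
                             "min": np.nan, "q25": np.nan, "median": np.nan,
                             "q75": np.nan, "max": np.nan})
            continue
        d = distance_rasters[code][row, col]
        rows_out.append({"class_code": code, "class_name": name, "n": len(d),
                         "min": float(np.min(d)), "q25": float(np.quantile(d, 0.25)),
                         "median": float(np.median(d)), "q75": float(np.quantile(d, 0.75)),
                         "max": float(np.max(d))})
    return pd.DataFrame(rows_out)


def plot_profile(
    species_id: str,
    occ: OccurrenceTable,
    elevation: RasterLayer,
    bio1: RasterLayer,
    bio12: RasterLayer,
    landcover: RasterLayer,
    path,
    background_mask: np.ndarray | None = None,
) -> None:
    """Three-panel species atlas page: elevation histogram, climate-space
    scatter over the background cloud, and land-cover distance boxplots."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = occ.subset(species_id)
    hist = elevation_histogram(sub, elevation)
    env = climate_envelope(sub, bio1, bio12, background_mask)
    dist = landcover_distances(sub, landcover)

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    axes[0].stairs(hist.counts, hist.bin_edges, fill=True, color="steelblue")
    axes[0].set_xlabel("elevation (m)")
    axes[0].set_ylabel("records")
    axes[0].set_title(f"{species_id} — elevation")

    if env["background"] is not None:
        axes[1].scatter(env["background"]["BIO1"], env["background"]["BIO12"],
                        s=2, c="0.8", label="background")
    axes[1].scatter(env["climate_points"]["BIO1"], env["climate_points"]["BIO12"],
                    s=8, c="crimson", label="records")
    axes[1].set_xlabel("BIO1 (°C)")
    axes[1].set_ylabel("BIO12 (mm)")
    axes[1].set_title("climate space")
    axes[1].legend(frameon=False, fontsize=7)

    present = dist[dist["n"] > 0]
    stats = [
        {"label": str(r["class_code"]), "med": r["median"], "q1": r["q25"],
         "q3": r["q75"], "whislo": r["min"], "whishi": r["max"], "fliers": []}
        for _, r in present.iterrows()
    ]
    if stats:
        axes[2].bxp(stats, showfliers=False)
    axes[2].set_xlabel("land-cover class")
    axes[2].set_ylabel("distance (km)")
    axes[2].set_title("distance to class")

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def species_profile(
    species_id: str,
    occ: OccurrenceTable,
    elevation: RasterLayer,
    bio1: RasterLayer,
    bio12: RasterLayer,
    landcover: RasterLayer,
    background_mask: np.ndarray | None = None,
    distance_rasters: dict[int, np.ndarray] | None = None,
) -> dict:
    """Assemble the full per-species profile (histogram, envelope, distances)."""
    sub = occ.subset(species_id)
    hist = elevation_histogram(sub, elevation)
    env = climate_envelope(sub, bio1, bio12, background_mask)
    dist = landcover_distances(sub, landcover, distance_rasters)
    return {
        "species_id": species_id,
        "n_records": len(sub),
        "elevation_hist": {"bin_edges": hist.bin_edges.tolist(),
                           "counts": hist.counts.tolist(),
                           "n_valid": hist.n_valid, "n_dropped": hist.n_dropped},
        "climate_summary": env["climate_summary"],
        "landcover_stats": dist.to_dict(orient="records"),
    }
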