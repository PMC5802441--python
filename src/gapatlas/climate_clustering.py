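"""Standardized PCA of the bioclim suite and equal-variance climatic clusters.

The clustering method partitions the retained principal-component space
into rectangular bins such that each full division along a component
accounts for a fixed fraction (``theta``, default 10%) of the total
explained variance, walking outward from a chosen origin (default the
component's zero).  Because components are ordered by eigenvalue, later
components receive fewer divisions.  Clusters are the Cartesian product of
the per-component bins, numbered left-to-right then bottom-to-top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .geodata_io import OccurrenceTable, RasterLayer, pixel_area_km2
from .synthetic_data import BIOCLIM_KEYS

logger = logging.getLogger("gapatlas")


@dataclass
class PcaModel:
    """Standardized-PCA model over study-area pixels.

    ``loadings`` has one column per component (orthonormal);
    ``explained_fraction`` is each eigenvalue divided by the total variance
    of all standardized variables (= the number of variables).
    """

    variables: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray          # (n_vars, n_vars)
    eigenvalues: np.ndarray       # (n_vars,)
    explained_fraction: np.ndarray
    scores: np.ndarray            # (n_pixels, retained)
    retained: int
    pixel_index: np.ndarray       # (n_pixels, 2) row/col of each score row

    def loadings_table(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.retained)]
        df = pd.DataFrame(self.loadings[:, : self.retained], index=self.variables, columns=cols)
        df.loc["eigenvalue"] = self.eigenvalues[: self.retained]
        df.loc["explained_fraction"] = self.explained_fraction[: self.retained]
        return df


@dataclass
class ClusterPartition:
    """Per-component breakpoints and the per-pixel cluster labels."""

    theta: float
    origin: float
    breakpoints: list[np.ndarray]          # per retained component, ascending, includes origin
    bins_per_component: list[int]
    side_bins: list[tuple[int, int]]       # (bins below origin, bins at/above origin)
    labels: np.ndarray = field(default_factory=lambda: np.empty(0, int))  # per score row

    @property
    def n_clusters(self) -> int:
        return int(np.prod(self.bins_per_component))


def fit_pca(
    bioclim: dict[str, RasterLayer],
    study_mask: np.ndarray,
    variables: tuple[str, ...] = BIOCLIM_KEYS,
    retained: int = 2,
) -> PcaModel:
    """Fit a PCA to z-standardized bioclim variables over study pixels.

    Each variable is standardized to mean 0 / sd 1 (ddof=1) over the study
    pixels before the eigen-decomposition, so the eigenvalues sum to the
    number of variables.  Component signs follow the convention that each
    column's largest-magnitude loading is positive.
    """
    rows, cols = np.nonzero(study_mask)
    if len(rows) < len(variables):
        raise ValueError(f"need at least {len(variables)} pixels with complete data")
    X = np.column_stack([bioclim[v].values[rows, cols] for v in variables])
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.isclose(sds, 0)
    if zero.any():
        bad = [v for v, z in zip(variables, zero) if z]
        raise ValueError(f"constant variable(s) cannot be standardized: {bad}")
    Z = (X - means) / sds

    pca = PCA(n_components=len(variables), svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T.copy()           # columns = components
    eigenvalues = pca.explained_variance_.copy()  # ddof=1 → sums to n_vars

    # sign convention: the largest-|loading| entry of each column is positive
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]

    scores = Z @ loadings[:, :retained]
    return PcaModel(
        variables=list(variables),
        means=means,
        sds=sds,
        loadings=loadings,
        eigenvalues=eigenvalues,
        explained_fraction=eigenvalues / len(variables),
        scores=scores,
        retained=retained,
        pixel_index=np.column_stack([rows, cols]),
    )


def project(model: PcaModel, values: dict[str, np.ndarray]) -> np.ndarray:
    """Project climate values into the fitted PC space (no refit)."""
    missing = [v for v in model.variables if v not in values]
    if missing:
        raise ValueError(f"missing variable(s): {missing}")
    X = np.column_stack([np.asarray(values[v], float) for v in model.variables])
    Z = (X - model.means) / model.sds
    return Z @ model.loadings[:, : model.retained]


def score_contributions(model: PcaModel) -> np.ndarray:
    """Per-pixel, per-component share of the total retained variance.

    c_ik = s_ik² / Σ_i Σ_k s_ik², so contributions over all study pixels
    and retained components sum to exactly 1.
    """
    s2 = model.scores**2
    return s2 / s2.sum()


def _walk_side(scores_side: np.ndarray, contrib_side: np.ndarray, theta: float,
               outward_ascending: bool) -> list[float]:
    """Accumulate contributions walking outward from the origin; each time
    the running sum reaches theta, close the bin, emit a boundary and
    restart the accumulator.

    ``outward_ascending`` is True on the positive side (walk toward +inf).
    Pixels with tied scores are consumed together so a boundary never splits
    a score value.  On the positive side the boundary is the first score
    beyond the crossing pixel; on the negative side it is the crossing
    pixel's own score — both choices keep the crossing pixel inside the
    completed bin under half-open lower-inclusive intervals.
    """
    order = np.argsort(scores_side, kind="stable")
    if not outward_ascending:
        order = order[::-1]
    s = scores_side[order]
    c = contrib_side[order]
    boundaries: list[float] = []
    acc = 0.0
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        acc += float(c[i : j + 1].sum())
        if acc >= theta - 1e-12:
            # close the bin: it holds >= theta (and < theta + one pixel's
            # contribution), then restart the accumulator
            acc = 0.0
            if j + 1 < n:  # the outermost partial run forms the final bin
                boundaries.append(float(s[j + 1]) if outward_ascending else float(s[j]))
        i = j + 1
    return boundaries


def equal_variance_breakpoints(model: PcaModel, theta: float = 0.10,
                               origin: float = 0.0) -> ClusterPartition:
    """Delimit each retained component into bins of equal explained variance.

    For each component, pixels are walked outward from ``origin`` in the
    negative and positive directions separately, accumulating per-pixel
    variance contributions; whenever the accumulated contribution reaches
    ``theta`` a bin closes and a breakpoint is emitted.  Each side's number
    of bins is ceil(side share / theta), so the outermost bin may be thin.
    """
    if theta <= 0 or theta > 1:
        raise ValueError("theta must lie in (0, 1]")
    contrib = score_contributions(model)
    breakpoints: list[np.ndarray] = []
    bins: list[int] = []
    side_bins: list[tuple[int, int]] = []
    for k in range(model.retained):
        s = model.scores[:, k]
        c = contrib[:, k]
        neg = s < origin
        pos = ~neg
        b_neg = _walk_side(s[neg], c[neg], theta, outward_ascending=False)
        b_pos = _walk_side(s[pos], c[pos], theta, outward_ascending=True)
        # one more bin per side than interior boundaries (the outermost
        # partial accumulation forms the final bin); an empty side has none
        n_neg = (len(b_neg) + 1) if neg.any() else 0
        n_pos = (len(b_pos) + 1) if pos.any() else 0
        bp = np.array(sorted(b_neg) + [origin] + b_pos)
        if not np.all(np.diff(bp) > 0):
            raise RuntimeError("breakpoints are not strictly increasing")
        breakpoints.append(bp)
        bins.append(max(n_neg + n_pos, 1))
        side_bins.append((n_neg, n_pos))
    return ClusterPartition(theta=theta, origin=origin, breakpoints=breakpoints,
                            bins_per_component=bins, side_bins=side_bins)


def bin_lookup(scores_k: np.ndarray, partition: ClusterPartition, k: int) -> np.ndarray:
    """Half-open lower-inclusive bin index along component ``k`` (0-based,
    counted from the most negative bin), clamped to the end bins."""
    bp = partition.breakpoints[k]
    n_bins = partition.bins_per_component[k]
    n_neg, _ = partition.side_bins[k]
    # with n_neg >= 1 the origin is an interior boundary and len(bp) ==
    # n_bins - 1; with n_neg == 0 the origin bounds an empty half-line and
    # the lookup index shifts down by one
    offset = 1 if n_neg == 0 else 0
    idx = np.searchsorted(bp, np.asarray(scores_k, float), side="right") - offset
    out = (idx < 0) | (idx > n_bins - 1)
    if out.any():
        logger.info("bin_lookup: clamped %d score(s) on component %d", int(out.sum()), k + 1)
    return np.clip(idx, 0, n_bins - 1)


def assign_clusters(model: PcaModel, partition: ClusterPartition) -> ClusterPartition:
    """Label every study pixel with its cluster id.

    Labels run 1..n1·n2, numbered left-to-right along PC1 then bottom-to-top
    along PC2 (label 1 = bottom-left corner of PC space).  Scores outside
    the outermost breakpoints are clamped to the end bins (logged).
    """
    partition.labels = labels_for_scores(model.scores, partition)
    return partition


def labels_for_scores(scores: np.ndarray, partition: ClusterPartition) -> np.ndarray:
    """Cluster labels for arbitrary score rows (projection lookup)."""
    n1 = partition.bins_per_component[0]
    i1 = bin_lookup(scores[:, 0], partition, 0)
    if len(partition.bins_per_component) == 1 or scores.shape[1] == 1:
        return (i1 + 1).astype(int)
    i2 = bin_lookup(scores[:, 1], partition, 1)
    return (i2 * n1 + i1 + 1).astype(int)


def cluster_raster(model: PcaModel, partition: ClusterPartition,
                   template: RasterLayer) -> RasterLayer:
    """Per-pixel cluster labels as a categorical raster on the template grid."""
    out = np.full(template.shape, -1, dtype=int)
    rows, cols = model.pixel_index[:, 0], model.pixel_index[:, 1]
    out[rows, cols] = partition.labels
    return RasterLayer(out, template.origin, template.resolution, nodata=-1, kind="categorical")


def cluster_coverage(
    occ: OccurrenceTable,
    model: PcaModel,
    partition: ClusterPartition,
    template: RasterLayer,
    round_dp: int = 2,
) -> pd.DataFrame:
    """Per-cluster sampling summary.

    For each cluster: number of distinct species with records inside it, the
    number of sampled localities (distinct pixels of the analysis resolution
    containing at least one record), the percentage of the cluster's pixels
    sampled, and the cluster area in km².
    """
    from .summaries import percent

    labels_r = cluster_raster(model, partition, template)
    row, col = template.rowcol(occ.lon, occ.lat)
    nrow, ncol = template.shape
    inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    row, col = row[inside], col[inside]
    species = occ.records["species_id"].to_numpy()[inside]
    rec_labels = labels_r.values[row, col]

    _, lats = template.centers()
    px_rows = model.pixel_index[:, 0]
    px_area = pixel_area_km2(lats[px_rows], template.resolution)

    rows_out = []
    for cl in range(1, partition.n_clusters + 1):
        in_cl = rec_labels == cl
        n_species = len(set(species[in_cl]))
        localities = len(set(zip(row[in_cl], col[in_cl])))
        n_pixels = int((partition.labels == cl).sum())
        pct = percent(localities, n_pixels, dp=round_dp) if n_pixels else 0.0
        area = float(px_area[partition.labels == cl].sum())
        rows_out.append({"cluster": cl, "n_species": n_species,
                         "localities_sampled": localities,
                         "percent_sampled": pct,
                         "area_km2": round(area, round_dp)})
    return pd.DataFrame(rows_out)
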