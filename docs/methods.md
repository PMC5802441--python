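# Methods

## Coordinate and area conventions

All layers live in geographic coordinates (WGS84 decimal degrees). The
analysis graticule (default 10 arc-minutes) snaps to multiples of the cell
size from the (0°, 0°) origin, so the same boundary polygon always yields
the same grid. Cell and pixel intervals are half-open —
[west, east) × [south, north) — so every point belongs to exactly one cell
and a record on a shared edge goes to the cell to its east/north-east; the
raster's outer north edge is inclusive so border points are not lost.

Pixel areas use the spherical cos-latitude approximation: a pixel of
d_lon × d_lat degrees centered at latitude φ covers
(d_lat · 111.32 km) × (d_lon · 111.32 km · cos φ). At subtropical
latitudes (≈ 17–26° N, the default synthetic domain) this deviates from
the ellipsoidal value by well under 1% and is fully deterministic. Polygon
areas in km² integrate the same correction over thin latitude slabs.

## Climatic clustering

Twelve bioclim variables (BIO1, 4, 5, 6, 7, 10, 11, 12, 13, 16, 18, 19)
are z-standardized (mean 0, sd 1 with ddof = 1) over study pixels, so the
PCA eigenvalues sum to 12 and each eigenvalue divided by 12 is the
fraction of total variance explained. Component signs follow the
convention that each loading column's largest-magnitude entry is positive,
which makes runs reproducible. Two components are retained by default.

The partition of PC space works per component. Define each pixel's
contribution c_ik = s_ik² / Σ_i Σ_k s_ik² over the retained components, so
all contributions sum to one. Walking outward from the origin (default 0)
separately in the negative and positive directions, contributions are
accumulated; each time the running sum reaches θ (default 0.10) a bin is
closed, a boundary emitted, and the accumulator reset. Consequences:

- each fully accumulated bin holds between θ and θ + (that side's largest
  single-pixel contribution) of the total retained variance;
- the outermost accumulation on each side forms a final, possibly thin,
  bin with no emitted boundary;
- the number of bins per side is ceil(side share / θ), so later components
  (smaller eigenvalues, smaller shares) receive no more bins than earlier
  ones.

Boundary placement under half-open lower-inclusive intervals: on the
positive side the boundary is the first score *after* the crossing pixel;
on the negative side it is the crossing pixel's own score. Both keep the
crossing pixel inside the bin it completed. Tied scores are consumed
together so a boundary never splits a score value. Cluster labels are the
row-major index over (PC2 bin from bottom, PC1 bin from left), numbered
1..n1·n2 left-to-right then bottom-to-top; scores outside the training
range (projected protected-area or species climates) clamp to the end bins
and the clamp is logged.

The walker is isolated behind `equal_variance_breakpoints` so an
alternative scheme (e.g. ignoring the origin) can be swapped without
touching label assignment.

## Ecological profiles

Elevation histograms use half-open 100 m bins, with all negative
elevations folded into one [min, 0) bin. The climate envelope reports each
record's (BIO1, BIO12) pair against the background cloud of all study
pixels. Land-cover distances are computed per class with a Euclidean
distance transform on the class mask, with anisotropic pixel sampling in
km derived from a world equidistant cylindrical projection (standard
parallel 0°: 1° of longitude = 1° of latitude = 111.32 km). Distances are
center-to-center at raster resolution, so a record on a pixel of class c
is at distance 0 from c; classes absent from the raster are reported with
n = 0 rather than silently dropped. The projection choice trades geodesic
accuracy for fidelity to the standard boxplot-distance workflow; at high
latitudes east–west distances are overestimated.

## Range estimation and gap analysis

AOO marks the analysis pixels (~1 km) containing at least one record;
duplicate records collapse to one pixel. The 4 km² variant aggregates
pixels into 2×2 blocks and counts each occupied block's full four-pixel
footprint, so the 4 km² area is never smaller than the 1 km² area.

EOO takes the convex hull of the record coordinates (requires ≥ 3
non-collinear points; otherwise the estimate falls back to the AOO pixel
set and is flagged `fallback_used`), keeps the analysis pixels whose
centers lie inside the hull and whose elevation passes the altitude
filter, and unions in the occupied pixels themselves. The union term
guarantees AOO ⊆ EOO even when a record pixel's center falls marginally
outside the hull of the point coordinates. Two filter modes: the default
`observed-range` keeps pixels within the [min, max] of the records'
elevations (conservative; never excludes an occupied pixel); `mean-band`
keeps pixels within mean ± k·sd of the record elevations. The mode is
recorded in all outputs.

A pixel (or block) counts as protected iff its center lies inside any
protected-area polygon. Center containment, rather than partial overlap,
keeps the bias for very small reserves bounded and deterministic — the
smallest reserves in the shipped register are far below one pixel.
Percentages are rounded half-up to 2 decimals, matching conventional table
formatting. Species are scored against 17% and 12% targets per estimator
and combined (a species passes combined if it passes under either
estimator), with endemic-only breakdowns and zero-protection counts.

## Synthetic study systems

The generator is the package's test bed, not a climate model. Elevation is
a low plain plus two anisotropic Gaussian massifs (a high northern arc and
a lower southern coastal plateau) plus smooth noise. BIO1 follows a
−6.5 °C/km lapse rate from elevation; BIO12 combines a dry baseline, an
orographic term, and a coastal monsoon band; the remaining ten variables
are deterministic transforms of these plus smooth noise constructed so the
type invariants (BIO5 ≥ BIO1 ≥ BIO6; BIO12 ≥ BIO13 ≥ 0; BIO12 ≥ BIO16)
hold at every pixel for every seed. Land cover is assigned by
elevation/precipitation thresholds blended with a smooth categorical noise
field, using exactly the nine classes of the atlas convention. Protected
areas are irregular blobs with log-uniform radii spanning several orders
of magnitude — echoing real national networks whose reserves range from
ponds to thousands of km² — rescaled by fixed-point iteration so their
union covers the requested fraction of the country (default 4%).

Species niches are Gaussian in (BIO1, BIO12) space, drawn from four
archetypes (generalist, montane, desert, mesic); defining suitability in
climate rather than geographic space gives the climate-envelope profiler a
recoverable truth. A species' true range is the pixels with suitability
≥ 0.5; records are sampled from the true range proportional to
suitability × an uneven effort surface (effort_bias = 0 gives uniform
effort), jittered within their pixel. `exhaustive=True` instead emits one
record at every occupied pixel center, which is what the recovery tests
use: under exhaustive sampling the pipeline's AOO, per-cell richness and
percent-protected must reproduce the generator's stored truth. Default
conditions: a 2° × 2° domain at 0.01° (~1 km) resolution, 30 species,
3–60 records per species, endemic/venomous attribute prevalences of 20/101
and 9/101. One root seed feeds named child streams per component, so
identical calls are bit-identical.

What the generator does *not* emulate: temporal climate variability,
spatially correlated taxonomic identification error, presence-only biases
tied to roads or settlements, and coastline/island geometry. Passing tests
therefore demonstrate algorithmic correctness and ground-truth
recoverability, not that the pipeline's estimates are unbiased on any real
national dataset.

## Numerical choices and problem sizes

- Breakpoint accumulation uses a 1e−12 tolerance when testing whether a
  running sum reached θ, so exact-multiple splits (the symmetric toy case)
  close their bin.
- PCA uses a full SVD; score/loading checks in the test suite run at
  1e−8 to 1e−10.
- Degenerate inputs: constant climate variables abort the PCA naming the
  variable; zero-area study polygons abort grid construction; species with
  empty ranges yield NaN protection percentages and are flagged, never
  silently dropped.
- The test suite and the acceptance script run worlds of 100×100 to
  200×200 pixels with 8–30 species — sizes chosen so the full suite
  completes in well under a minute on one core while every code path
  (fallbacks, empty clusters, absent land-cover classes) is still
  exercised.

## Reference data

`src/gapatlas/data/oman_protected_areas.csv` is the published register of
Oman's 22 protected areas (name, management type, area, perimeter, year).
It is used by the acceptance script's arithmetic checks (total area
12,916.52 km²; 3.91% of ~330,000 km²) and is available to users as a
realistic size distribution for protected-area networks.
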