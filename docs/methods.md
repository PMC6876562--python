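# Methods

This note documents the models, parameter choices and numerical
conventions behind phenocloud, and what the synthetic-data tests do and
do not demonstrate about real UAV data.

## Input model and conventions

The sole algorithmic input is a 3D point cloud (x, y, z) in a projected,
metric CRS; z is altitude above sea level.  Geographic (lat/lon) CRSs are
rejected at load time because every threshold in the pipeline is in
metres.  No reprojection is performed: coordinates stay in the file's
native frame.

All spatial binning — DTM tiles, the crown grid, voxels — uses half-open
intervals [min, max), so a point on a shared border is counted exactly
once.  Grid origins are floor-aligned to the cell size
(⌊min/size⌋ · size), which makes every raster independent of point order.

LAS 1.1–1.4 is read with a built-in minimal reader (only x, y, z are
decoded; intensity, RGB and classification are read past and ignored);
LAS 1.2 is written.  Compressed LAZ is not supported.  Normalized heights
are dropped on write by default; with `keep_heights=True` they are stored
in the GPS-time field of point format 1 — a package-local convention,
flagged in the header's generating-software string.

## Terrain model

* **Tile size: 2 m** (default).  Sized to young-tree dimensions and the
  planting patterns: a 2 m tile under a young tree still receives mostly
  ground returns.
* **Ground rule: mean of the k = ⌈0.15 n⌉ lowest points, k ≥ 1.**  The
  ceiling rule guarantees a non-empty set for sparse tiles; 15 % is small
  enough to stay below the canopy and large enough to average sensor
  noise.
* The DTM is **piecewise-constant per tile** — no within-tile
  interpolation.  Smoother terrain products (TIN, kriging) are
  deliberately out of scope; the DTM exists to normalize heights.
* **Empty tiles** are filled from the nearest non-empty tile centre (ties
  broken toward the lower elevation) and flagged in `fill_mask`.
* Negative normalized heights (ground noise below the tile estimate) are
  retained until tree-point classification, where the 0.3 m threshold
  removes them; keeping them preserves DTM diagnostics.

A property worth knowing: under Gaussian vertical noise of width σ, the
mean of the lowest 15 % of a flat tile's points sits at −(1/0.15)·φ(z₀.₁₅)·σ
≈ −1.554 σ below the true surface (≈ −3.1 cm at σ = 2 cm).  This datum
offset is inherent to any lowest-points ground rule; it is common to all
tiles, so it cancels in relative quantities (normalized heights are
shifted up by the same amount the terrain is shifted down, and
tile-to-tile precision is two orders of magnitude better than the
offset).  DTM agreement is therefore scored by regression against
reference elevations (`compare_dtm`), whose R² and fitted-line RMSE are
datum-tolerant — the same logic by which a photogrammetric DTM is
compared against an official reference DTM with a different datum.  The
test suite asserts both the sub-centimetre bias-corrected RMSE and that
the measured offset matches the analytic −1.554 σ.

## Tree detection

* **Height threshold 0.3 m, inclusive (≥).**  Suited to very young trees
  on bare soil; the boundary point is kept because the threshold is a
  "this high counts as tree" rule.
* **8-connectivity** for crown merging: diagonal adjacency connects.
  4-connectivity fragments sparse young crowns whose occupied cells often
  touch only at corners.
* **Minimum crown size: 3 cells (0.03 m²), configurable.**  Isolated
  photogrammetric outliers otherwise appear as spurious one-cell trees.
* **Interior filling:** background pockets not connected to the grid
  border are merged into the enclosing crown (majority label of the
  surrounding cells, ties toward the lower label) and tracked in
  `interior_mask`.  Filling never changes the crown count.
* Labels are renumbered in raster-scan order of each component's first
  cell, so outputs are bit-reproducible.
* **Hedgerow splitting:** each crown cell within 1 m (the in-row planting
  distance scale) of at least one seed is relabelled to the nearest
  seed's id, ties toward the lower id — nearest-seed is the natural
  splitter of a merged canopy wall at the midline between trees.  Cells
  outside every seed radius keep component labels renumbered above the
  seed-id range and are flagged unassigned.  The operation is idempotent
  and invariant to seed order.

## Voxel layer and crown volume

Voxels are 0.1 m cubes; k = 0 is the first decimetre above the terrain of
the cell's tile, so slicing follows normalized height.  A voxel is
occupied by presence (≥ 1 point), which makes the representation
insensitive to oversampling.  Points with negative normalized height are
excluded (no k < 0).  The voxel size equals the crown-grid cell size by
construction (enforced in the pipeline config): one 0.1 m resolution for
both rasters, fine enough for sub-metre crowns, coarse enough that a
photogrammetric cloud reliably occupies the voxels it intersects.

Interior (filled, point-free) crown cells have no voxels of their own.
They receive the rounded half-up mean of the column counts of their
point-bearing 8-neighbour crown cells, or 0 with no such neighbour.  This
is a conservative stand-in for the unobserved crown core; the plausible
alternatives (count nothing; fill the full span between neighbouring
column extents) bracket it from below and above.

Crown volume is Σ column counts × (0.1 m)³ over the tree's cells.  Two
useful exact identities: with no interior cells the volume equals
voxel volume × number of occupied voxels, and volume can never exceed
projected area × height when the tree threshold is at least three voxel
heights (tree points occupy only slices k ≥ 3).

## Traits

* **Height** is the maximum normalized point height of the tree — point
  heights, not voxel tops, to avoid a second discretization.
* **Length** = largest distance between two crown-cell centres + one cell
  size; **width** = extent of the centres perpendicular to the length
  axis + one cell size; width ≤ length by construction.  The one-cell
  correction compensates the half-cell truncation at each end; against a
  brute-force corner-to-corner diameter the centre-pair approximation is
  within (√2 − 1) · cell ≈ 4 mm.  Orientation is free (not row-aligned):
  nothing in the footprint knows the planting direction.
* **Location** is the crown-cell centroid.
* Exports: CSV (fixed column set) and GeoJSON polygons (dissolved cell
  boundaries).  A "shapefile-safe" dialect truncates attribute names to
  the 10-character DBF limit for downstream conversion.

## Validation statistics

Field crown geometry uses the tape-measure idealizations
A = π((D₁+D₂)/4)² (circle on the mean diameter; symmetric in D₁, D₂) and
V = A·H/3 (cone).  Agreement is summarized by OLS R² (estimated ~
observed), RMSE about the **1:1 identity line** (the natural reading of a
scatter plot against the 1:1 line; switchable to residuals about the
fitted line, which `compare_dtm` uses for datum-tolerant DTM comparison),
nRMSE as a percentage of the observed mean, and bias
(ȳ − x̄)/x̄ × 100.  Percentages are rounded to one decimal for reporting;
population summaries use the sample (n − 1) standard deviation, with a
single observation reported as SD 0 by convention.

Tree pairing for validation is by shared id when available, otherwise
greedy one-to-one nearest-neighbour by location within a distance cap.
Detected component labels are scan-ordered, not planting-ordered, so
location pairing is the correct mode whenever ids did not come from a
seed table.

## Synthetic orchards

The generator emulates the two studied training systems: intensive
(7 m in-row × 5 m rows, ≈ 286 trees/ha) and hedgerow (1.75 × 5 m,
≈ 1143 trees/ha).  Defaults mirror the study conditions: tree heights
drawn from 0.6–3.25 m, cloud densities ≈ 4,500 pts/m², flat ground,
σ = 2 cm Gaussian vertical noise.  Canopies are cones (or ellipsoids)
sampled mostly on the outer envelope (`surface_bias = 0.9`), with surface
density proportional to local circumference — so point counts thin toward
the apex, reproducing the known cause of photogrammetric height
underestimation (with n surface points, the expected count in the top
fraction t of a cone is n·t²).  `canopy_density` is points per m² of
projected crown area; `min_canopy_points` optionally floors the per-tree
count when a study condition prescribes one.  Terrain can be flat, sloped
or undulating.  Everything is deterministic given the spec seed, and the
truth table carries analytic values (projected area π·D₁·D₂/4, cone
volume π·D₁·D₂·H/12).

What the generator does **not** model: occlusion shadows and
reconstruction dropouts, matching artefacts, georeferencing error,
radiometry, wind-blurred canopies, weeds/cover crops (trunk points below
the threshold can be enabled separately).  Passing recovery tests
therefore demonstrates the correctness of the algorithmic chain under the
stated sampling model — not field accuracy on arbitrary real imagery,
which depends on flight configuration and reconstruction quality.

## Problem sizes in tests

The default suite runs orchards of 6–30 trees at ground densities of
800–4,500 pts/m² (clouds of 0.3–5 M points), chosen so the full suite and
the acceptance script each finish in minutes on a single CPU while
keeping every stage in its realistic operating regime.  The recovery
acceptance run uses the full study conditions: 30 cone trees, heights
1–3 m, ≥ 3,000 generated points per tree, σ = 2 cm, 4,500 pts/m² ground.

## Known limitations

* No occlusion correction: crown volume is systematically below the
  geometric cone value for envelope-only clouds (≈ −25 % in synthetic
  runs); the same direction of error is expected, for different reasons,
  against circle/cone field idealizations of real crowns.
* The DTM datum offset under noise (−1.554 σ) shifts all elevations
  together; absolute elevations inherit it even though traits do not.
* A tree whose crown never rises 0.3 m above the terrain is invisible by
  construction.
* Merged hedgerow cells farther than the seed radius from every seed stay
  unassigned rather than being force-attributed; they are reported so the
  caller can widen the radius deliberately.
* LAZ input and Shapefile output require external conversion.
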