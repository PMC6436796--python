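# Methods

This note documents the models and procedures implemented in sdmflow, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data tests do and do not demonstrate.

## Coordinate and raster conventions

All data live on a single geographic template grid: WGS84 decimal degrees,
north-up, row-major, origin at the north-west corner, half-open cells
`[edge, edge + step)`. Derived rasters (suitability, binaries, expert
maps) always preserve the template grid exactly, so cellwise algebra
between pipeline stages is safe by construction.

Metric quantities — buffer radii, thinning and dedup distances, areas —
are computed in a local equirectangular projection about the region
centroid (`x = R·cos(lat₀)·Δlon`, `y = R·Δlat`, R = 6371.0088 km).
Exact great-circle (haversine) distances are used for pairwise point
distances in thinning. At the national extents and 1–200 km scales this
toolkit targets, the projection error is far below every tolerance used
(the unit tests check a 10-km buffer's area against πr² within 1%).
GeoTIFF I/O writes the standard georeferencing tags (ModelPixelScale,
ModelTiepoint, GeoKeyDirectory, GDAL nodata) directly through `tifffile`;
only single-band, north-up, EPSG:4326 rasters are supported, which is all
the pipeline produces.

## Occurrence curation

*Documentation score.* "Most documented record" is defined as the count of
populated fields among event date, elevation, locality, institution,
collection code, catalog number, recorder and source occurrence id. Ties
break to the earliest permanent identifier, making dedup fully
deterministic.

*Automated flags.* The rule engine is configurable; the default set covers
the error classes expert networks are asked to catch: MISSING_COORDS,
ZERO_COORDS, OUT_OF_REGION (reference polygon), COORD_SWAP (the swapped
point falls inside the region while the original does not — a lat/lon
transposition heuristic, non-blocking since it is only a suspicion),
ELEV_MISMATCH (|recorded − DEM| > 500 m by default, non-blocking),
DUPLICATE_EXACT (repeated provenance tuple), FUTURE_DATE. Rules are pure
functions of (record, reference layers); re-running the checks is a no-op,
and rules whose reference layer is absent are skipped with a warning
rather than failing the batch.

*Dedup grid.* When no raster template is supplied, the 1-km dedup cells
are a km lattice in the local metric projection anchored at the data
bounding box, so the cell size is exactly the configured distance at any
latitude.

*Audit log.* Append-only; each edit stores old and new values. A revert
replays the record's entries newest-first as compensating edits, so the
original state is restored field-by-field while the log keeps the
complete history. Only coordinates, taxon and manual flags are editable;
identifiers and provenance are immutable.

## The modeling ladder

Method choice is a function of the clean-occurrence count: 1–2 → 10-km
buffer, 3–4 → convex hull, 5–9 → Bioclim, ≥10 → MaxEnt-style model. The
count of five sits on a boundary; it is assigned to Bioclim because the
statistical model is preferred whenever it is feasible. A degenerate
(collinear) hull at n = 3–4 falls back to the buffer method with a
warning. All outputs are clipped to the accessible area M; when experts
provide no M polygon, the default is a 200-km buffer around the
occurrences clipped to the study region — a deliberately generous
accessible-area hypothesis for background sampling.

*Thinning* is greedy: repeatedly drop the point with the most neighbours
closer than the threshold, ties broken by a seeded shuffle. This tends to
maximise the retained count and is deterministic per seed. The threshold
itself is a user input: the right value depends on record density and
spatial autocorrelation of the data at hand, which no library default can
know.

*Background sampling* draws one point per sampled cell (at the centroid),
without replacement, capped at the number of valid cells inside M with a
warning — a deliberate choice over sampling with replacement, since
duplicated background cells add no information to a presence–background
fit. Default size 10,000, standard practice for MaxEnt-style models.

*Bioclim.* Each variable contributes `2·min(p, 1−p)` where p is the
percentile rank (mean tie convention) of the cell's value among training
presences; outside the presence min–max envelope the contribution is 0;
cell suitability is the minimum over variables. The surface is 1 at the
multivariate presence median and 0 outside the envelope. A variable that
is constant across presences has a degenerate envelope: it scores 1 within
a small tolerance of that constant (with a warning) instead of poisoning
the whole model.

*MaxEnt-style model.* An L1-penalized logistic regression of presences
against background over an expanded feature basis — the standard open
equivalence of MaxEnt's Gibbs model. Features: variables min–max scaled
to [0, 1] on the training data; linear, quadratic, pairwise products, and
hinge features in both directions with knots at presence-value quantiles
(default 50 knots). The L1 weight is *per observation* — sklearn's `C` is
set to `1/(reg_multiplier · λ₀ · n_obs)` with λ₀ = 2×10⁻⁴ — so
regularization strength does not vanish as the background grows; λ₀ plays
the role of the default regularization magnitude in maxnet, and the
`reg_multiplier` exposed to tuning scales it exactly as MaxEnt's
regularization multiplier does. Exact numerical replication of the Java
MaxEnt implementation is a non-goal. Output uses the complementary
log-log transform `1 − exp(−e^H · raw)`, with `raw = exp(η)` normalised
over the background sample and H its entropy, which pins a typical
background cell near 1 − 1/e and bounds suitability in [0, 1].

*Spatial partitioning* is the block method: a rank-balanced median split
on longitude, then on latitude within each half (k = 4; k = 2 uses the
longitude split alone). Rank splitting keeps fold sizes within one per
split and is deterministic under coordinate ties. Background points are
assigned to blocks by the same split edges.

*Tuning.* Every combination of regularization multiplier × feature-class
set is scored by k-fold spatial cross-validation; the selection rule is
sequential: lowest mean test omission at the 10th-percentile training
threshold, then highest mean test AUC, then smallest multiplier, then grid
order. The full evaluation table is kept in the result. Bioclim models
are evaluated by the same block CV but not tuned (they have no
hyperparameters worth searching).

*Evaluation.* AUC is the rank statistic (probability a random presence
outranks a random background point, ties counting half); omission at t is
the fraction of test presences scoring strictly below t. Both are
validated against brute-force pair counting in the tests.

## Thresholding and expert feedback

The p-th percentile training presence threshold is the (k+1)-th smallest
training suitability value with k = ⌊n·p/100⌋. Values tied with the
threshold count as predicted present ("strictly below" omission
semantics), which guarantees training omission ≤ p% and makes the
threshold the *largest* value satisfying the bound — both properties are
checked against a brute-force scan over all candidate thresholds. Because
k is monotone in p, binaries nest: binary(30) ⊆ binary(20) ⊆ binary(10)
⊆ binary(0). The slider accepts any real p in [0, 30], not just the four
standard stops.

Feedback edits apply in a fixed, documented order: over-prediction
polygons clear cells, under-prediction polygons then set cells (an
explicit expert assertion of presence survives an overlapping
over-polygon), and the habitat mask vetoes last (an ecological constraint
trumps hand-drawn presence). The operation is idempotent. Expert maps are
the rasterized range polygon minus barriers, intersected with the
elevation band (requires a DEM) and allowed land-cover classes; the output
is always a subset of the rasterized range polygon.

## Registry

Lifecycle: `under_development → pending_validation → validated`, with
`reopen` starting a new version (new data or taxonomy changes trigger
re-validation) and an external-intake path that publishes peer-reviewed
submissions immediately. Approval requires the arithmetic mean of 1–5
credibility scores to reach 3; the quorum is configurable and defaults to
a single score, since the number of active experts varies widely between
groups. Fact-sheet statistics were chosen to serve IUCN criterion-B
assessment: model area (sum of presence-cell areas, latitude-corrected),
EOO (convex-hull area of presence-cell centres in the metric projection;
fewer than 3 cells degrades to the summed cell area), AOO (occupied
2×2-km cells × 4 km²), and the elevation range over presence cells. Note
EOO ≥ area always holds, but AOO can be smaller or larger than the model
area depending on cell size.

## Synthetic data: what it shows and what it does not

Landscapes are smoothed white noise (Gaussian blur, configurable radius)
standardized per layer, plus a south–north DEM ramp with smooth relief and
a 5-class land cover from a quantile-binned smooth field. Smoothed noise
gives realistic spatial autocorrelation at desk-scale speed; it does not
reproduce the long-range gradients, anisotropy or cross-correlations of
real climate surfaces. Virtual species are products of per-variable
Gaussian responses rescaled to maximum 1, with the true range at a
suitability cutoff. Occurrence tables inject zero coordinates, transposed
coordinates, provenance duplicates and out-of-range misidentifications at
configurable rates; the ground-truth labels travel in a side array, never
in the table, so curation benchmarks cannot read the answer key.

Passing the recovery benchmark (100 presences, 10,000 background, two
informative variables plus a distractor, held-out spatial block AUC > 0.8
and informative variables carrying the largest coefficient mass in ≥9/10
trials) shows the estimation machinery works when the model family matches
the truth. It does not show the pipeline is robust to niche shapes outside
the Gaussian family, strong sampling bias, or predictor collinearity
patterns of real climate data.

## Problem sizes and determinism

The canned experiments use 100×100 grids (~0.01° ≈ 1.1 km cells), 100–150
occurrence records, 10,000 background points, 4 spatial blocks and a
2×2 tuning grid — large enough to exercise every code path and produce
stable statistics while keeping a full test run in tens of seconds. Every
stochastic step takes an explicit seed (NumPy `default_rng`); pipeline
metadata records the seeds and settings used, and identical seeds
reproduce identical artifacts bit-for-bit.

## Known limitations

- Only EPSG:4326 single-band GeoTIFFs; no reprojection or resampling
  beyond nearest-neighbour alignment to a template.
- The equirectangular local projection is inappropriate for continental
  extents or high latitudes.
- Spatial partitioning supports 2 or 4 blocks (the standard block
  design), not arbitrary k.
- No target-group bias modeling beyond using supplied occurrences; no
  ensembles; no projection to future climates; environmental-variable
  selection is left to the user.
- The MaxEnt surrogate matches MaxEnt's model family and regularization
  structure, not its exact numerical output.
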