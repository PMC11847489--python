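# Methods

This note documents the models, conventions and design choices behind
`nichecast`, in the spirit of a software methods appendix: what is
computed, under which assumptions, with which defaults, and what the
synthetic experiments do and do not demonstrate.

## Spatial conventions

All layers share one geographic (WGS84) grid of square degree cells
(default 0.05°, ~5.5 km). The grid origin is the outer north-west corner
of cell (0, 0); row indices increase southward and a cell's value refers
to its center. Cell membership — for calibration-region masking and
protected-area overlap alike — is decided by the cell center (boundary
inclusive), so every km² figure is reproducible from the rule "a cell is
in a region iff its center is".

Cell areas use the exact spherical-quadrangle formula on the authalic
sphere, `A = R² Δλ (sin φ_top − sin φ_bottom)` with R = 6371.0088 km,
accurate to <0.3 % of an ellipsoidal computation at these scales.
Distances split by purpose: great-circle (haversine, same sphere) for
the 5.5 km thinning radius, where sub-meter discrepancies are
irrelevant, and the WGS84 ellipsoid (Vincenty's inverse method, with a
spherical fallback for near-antipodal degeneracies) for centroid-shift
distances and initial bearings, where the printed quantity is the
headline result. Rasters are stored as single-band ESRI ASCII grids — a
plain-text georeferenced format — and polygons as GeoJSON.

## Occurrence processing

Cleaning applies per-record predicates: coordinates present and within
world bounds; collection year present (unless `require_date=false`) and
≥ `min_year` (default 1965); inside the accepted-range polygons; outside
the optional land/exclusion polygons. Because each predicate is
per-record, the retained set is independent of filter order; the removal
report attributes each dropped record to the first failing filter in a
fixed order. Records with a year but no month/day count as dated.

Deduplication keeps the earliest-indexed record per grid cell, after
which thinning enforces a minimum pairwise great-circle distance
(default 5.5 km, matching one record per 0.05° cell). The thinning
algorithm repeats `n_attempts` (default 10) seeded passes of "remove the
record with the most neighbours closer than the minimum (random
tie-break)" and keeps the largest surviving set. On instances of ≤12
points this matches exhaustive maximum-subset search in the test suite;
the heuristic is not guaranteed optimal in general.

## The maximum-entropy model

Features per predictor: scaled linear `(x−min)/(max−min)`; quadratic
(square of the scaled linear); pairwise products of scaled linears; and
forward/reverse hinges at 50 knots per direction placed at background
quantiles strictly inside the variable's range. Scaling bounds and knots
come from the background sample. Constant variables contribute only a
flagged constant-zero linear feature.

Penalties follow the conventional per-class schedule:
linear/quadratic/product interpolate β over presence counts
(0, 10, 30, 100) → (1.0, 1.0, 0.2, 0.05); hinge uses a constant 0.5.
`β_j = RM · β_class(m) · s_j/√m` with `s_j` the feature's standard
deviation over presences (background fallback when zero). The table is
a module constant so alternates are pluggable.

The penalized objective is minimized over the split positive-part
parameterization λ = λ⁺ − λ⁻ with bound-constrained L-BFGS; this is a
smooth, convex, deterministic formulation of the L1 problem, and the
test suite pins it against an independent proximal-gradient solver on
small problems (agreement to 1e−4). Defaults: 500 iteration cap, 1e−5
convergence threshold, background a uniform sample (without replacement,
presences not excluded) of calibration-area cells capped at 10,000.
After fitting, the raw distribution sums to one over the background by
construction; entropy H feeds the cloglog output.

Variable importance: *percent contribution* is the normalized drop in
regularized training gain when all of a variable's features are removed
and the model refit. This refit-drop definition replaces the original
per-iteration path-attribution heuristic, which depends on optimizer
internals and is not well defined for a batch convex solver; refit-drop
measures the same quantity (how much gain the variable carries) in an
optimizer-independent way. *Permutation importance* is the normalized
drop in training AUC after shuffling one variable across
presence+background. Jackknife fits report leave-one-variable-out and
single-variable gains and AUCs. Replicates are bootstrap resamples of
the presences (background held fixed), with cellwise mean/sd rasters.

## Calibration and selection

Candidates are the cross product of RM values (default 0.5–4.0 step 0.5)
with all non-empty feature-class subsets (default base `lqph`): 120
specifications. Occurrences split 70/30 (seeded). The three screens:

- *Partial ROC*: per bootstrap iteration (default 500, resampling 50 %
  of test points with replacement), the (proportion-of-area-predicted,
  sensitivity) curve is integrated over sensitivity ≥ 1−E and divided by
  the area under the 1:1 line; p is the fraction of iterations with
  ratio ≤ 1. Thresholds sweep all unique raster values, capped at 1,000
  quantile-spaced values for large rasters.
- *Omission at E = 5 %*: the threshold is the ⌈E·n⌉-th smallest training
  score (the training minimum at E = 0); the rate is the fraction of
  test presences strictly below it. This quantile convention is pinned
  in tests because conventions differ between implementations.
- *ΔAICc ≤ 2*: k counts nonzero coefficients; raw scores are
  standardized to sum to one over all calibration-area data cells;
  AICc is undefined when n ≤ k+1. The ΔAICc reference pool contains
  only candidates already passing significance and omission.

The E-quantile omission threshold is computed on training data and is
therefore optimistic relative to a held-out split; measured test
omission concentrates slightly above E, and on an unlucky split every
candidate can fail the screen (in the motivating study only 46 of 120
candidates passed it). When no candidate passes all three screens the
pipeline records a warning and proceeds with the lowest-AICc candidate,
so downstream stages remain exercised; the selection flags themselves
are never relaxed.

The selected specification is refit on all occurrences as bootstrap
replicates (default 10) for the final model.

## Projection, MOP, change accounting

Scenario projection clamps each variable to its calibration range
before feature evaluation (variable-level clamping; equivalent to
feature-level clamping for the feature classes used), so projected
suitability never leaves the calibration response surface; an identical
scenario reproduces the calibration-period prediction bit for bit.
Static variables are carried over unchanged by the caller.

MOP standardizes variables by calibration mean/sd; scenario cells with
any variable outside its calibration min–max are strict extrapolation,
and elsewhere similarity is `1 − d/d_max` with d the mean Euclidean
distance to the nearest 10 % (configurable) of up to 10,000 subsampled
calibration cells.

MTSS is the smallest threshold maximizing sensitivity (presences ≥ t)
plus specificity (background < t), scanned over all pooled unique
scores in exact integer arithmetic — floating-point summation can break
exact ties by one ulp and return the wrong maximizer. Equality at the
threshold counts as suitable (the boundary case is unspecified in common
usage; this choice is pinned by tests). Change maps code cells
never-suitable/lost/gained/maintained; `maintained+lost = current` and
`maintained+gained = future` hold exactly by construction. Percentages
follow the two published conventions (category areas relative to the
current area; total change relative to the current area), and
protected-area overlap percentages are likewise relative to the
*current* total suitable area, the convention verified arithmetically
against the published tables in the test suite. Centroids are
area-weighted means of suitable cell centers on lon/lat (a guard raises
if the grid crosses the antimeridian).

## Synthetic landscapes

The generator emulates the structure of a marine climatological stack:

- five predictor fields (two active, three inert) on a 200×200 grid of
  0.05° cells, each a standardized Gaussian random field (low-pass
  filtered white noise, filter σ = 8 cells);
- true suitability `s = logistic(b0 + b1·v1 + b2·v2 + c2·v2²)` with
  (b0, b1, b2, c2) = (−2, 2, 1.2, −2): monotone in the first active
  variable, unimodal in the second (optimum at v2 = 0.3). The
  coefficients were chosen once so mean suitability is ≈ 0.14,
  matching the motivating study's suitable fraction of its calibration
  area (14.4 %);
- the first active field mixes a flat-topped super-Gaussian envelope
  (weight 0.85) with its noise field. This keeps suitable habitat
  compact and well inside the grid for every seed, which is what makes
  the translation scenario a known-answer experiment: with a
  statistically stationary field, translation slides the pattern onto
  itself and clips habitat at the boundary, attenuating the recovered
  centroid shift by tens of km;
- the default grid sits near the equator so a 1° eastward translation
  corresponds to ≈ 111.3 km everywhere on the grid;
- presences are drawn with probability proportional to suitability
  (optionally times a bias layer) and jittered within their cell;
- future scenarios translate the active fields by whole cells (edge
  values held) and/or add per-variable trends; protected areas are
  random rectangles grown until they cover a requested fraction of
  suitable habitat (±0.05).

What the synthetic experiments show: the full pipeline recovers a known
suitability surface (rank correlation ≥ 0.9), rejects pure-noise
predictors, detects a known range displacement (111 km east within
sampling error), and satisfies the exact accounting identities. What
they do not show: behaviour under real-world sampling bias, spatially
structured observer effort, predictor measurement error, coastline
masks, or niche truncation at the calibration-region boundary — the
generator's fields are complete and noise-free, so the recovery numbers
are upper bounds on what field data would give.

## Problem sizes and determinism

The test suite and the acceptance script use the standard scenario
(200×200 cells, 5 variables, 500 presences, 10,000 background cells)
for the stochastic recovery checks, a reduced 80×80 fixture for unit
tests of fitted-model behaviour, and a reduced candidate grid
(2 RM × 3 feature-class subsets) on a 120×120 landscape for the
end-to-end pipeline integration test; these sizes were chosen as the
smallest at which the recovery properties are stable. Every random
stage draws its seed deterministically from one master seed (stage-name
hashing), so a single integer reproduces an entire run, and all
generators are pure functions of (configuration, seed).

## Known limitations

- The threshold feature class and categorical predictors are not
  implemented (both were excluded in the motivating workflow).
- Only geographic (EPSG:4326) rasters are supported; no reprojection.
- The thinning heuristic is exact only at small n (verified ≤ 12).
- Percent contribution is refit-based and can differ numerically from
  the original software's path-attribution values, though rankings
  agree on all tested cases.
- MOP's subset fraction (10 %) is a convention; published analyses
  rarely report the value they used.
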