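# Methods

This note documents the modelling choices, defaults and limitations of
the `ensemblesdm` pipeline in the order the stages run.

## Grids, areas and formats

All rasters live on one north-up WGS84 lon/lat grid of square cells;
values belong to cell centers. Cell areas use the spherical-Earth band
formula A = R²·Δλ·(sin φ_N − sin φ_S) with the authalic radius
R = 6371.0 km — the conventional choice for coarse-grid area accounting;
ellipsoidal (WGS84) areas differ by well under the uncertainty of any
committee-weighted range estimate. A global 1° grid sums to 4πR²
exactly up to float rounding, which the test suite asserts.

Rasters are single-band GeoTIFFs with NaN nodata and the standard
georeferencing tags (pixel scale, tiepoint, geokey directory, GDAL
nodata), read and written through `tifffile`. Vector regions are
GeoJSON with a `label` property; rasterization assigns each cell to the
first polygon (in layer order) whose boundary-inclusive test covers the
cell center, so the result is always a partition and border cells are
resolved deterministically.

## Synthetic worlds

The generator emulates the statistical structure the analysis assumes,
not climate physics:

- **Layers** are Gaussian-smoothed white noise (kernel σ = 8 cells by
  default) blended half-and-half with an alternating-sign latitudinal
  gradient, standardised to mean 0 / SD 1. Layer 2 is constructed from
  layer 1 at a target correlation (default 0.9) so the collinearity
  filter always has work to do.
- **Future scenarios** add a per-layer mean shift scaled by horizon
  (×0.75, ×1.0, ×1.25, ×1.5 of the base shift for the four
  scenario/year combinations) plus an independent smoothed perturbation
  per pseudo-GCM (amplitude 0.3). This is enough to exercise committee
  averaging across GCMs and ordered scenario divergence; it does not
  emulate downscaling artefacts, teleconnections, or co-dependent GCMs.
- **The virtual species** responds to a named subset of layers through a
  product of Gaussians exp(−(v−μ)²/2σ²), rescaled so the modal cell is
  1. Nuisance layers have exactly zero effect, which parameter-recovery
  tests exploit.
- **Presences** are cells drawn without replacement with probability
  proportional to true suitability — presence-only sampling with no
  detection error or spatial survey bias, which real compilations
  certainly have. Passing recovery tests therefore shows the machinery
  is consistent, not that it is robust to biased sampling.
- **Regions** are a Voronoi tessellation of random seed points
  ("countries", an exhaustive partition) and random rectangles
  accumulated until their union is within ±20% of the target protected
  fraction (default 0.3 of the grid).

Defaults for the demo world: 100×100 grid of 0.1° cells, 6 layers with
2 informative (optima 0.5 and −0.3, widths 0.8 in standardised units),
150 presences, 5 countries, 2 pseudo-GCMs. These sizes keep a full run
near one minute while leaving every stage statistically non-trivial.

## Occurrence cleaning and calibration region

Cleaning drops rows with unparseable, missing or out-of-range
coordinates and collapses exact (lon, lat) duplicates; an optional
source-tag exclusion list removes non-natural records (trade or captive
sites). No spatial thinning is applied. The calibration region is the
set of cells whose centers lie within a Euclidean *degree-space* buffer
(default 1.0°) of any presence, optionally intersected with a domain
polygon. A geodesic buffer would differ at high latitude; the pipeline
operates in the tropics-to-subtropics band where the distinction is
minor, and the metric is configurable.

## Predictor selection

Correlations and VIFs are computed over valid cells inside the
calibration region only. The filter is two-stage and greedy: first,
while any pair has |r| > r_max (default 0.7), the member of the worst
pair with the larger VIF is dropped; then, while any VIF > vif_max
(default 3), the largest-VIF layer is dropped. Equal VIFs drop the
layer later in input order, making selection deterministic. Tests check
against exhaustive enumeration that the survivors are compliant and
that no dropped layer could be restored without breaking compliance.
Perfect collinearity returns a +inf VIF sentinel rather than raising.
A config-driven exclusion list substitutes for any manual screening of
artefact-prone layers. Model fitting uses the native grid; projection
rasters can be block-mean upscaled (output cell valid iff ≥ 50% of its
block is valid). The demo world is already coarse, so its config keeps
the projection at native resolution (`upscale_factor: 1`); with real
30-arc-second inputs a factor of 10 reproduces the usual
2.5-arc-minute projection resolution.

## Learners

All five expose `predict → [0, 1]` and run with fixed, recorded
hyperparameters — no tuning anywhere:

- **maxent_like**: standardised linear + quadratic features, logistic
  model with L1 penalty (C = 1), an exponential-family approximation in
  the spirit of MaxEnt.
- **regression_splines**: degree-1 (piecewise-linear) spline basis with
  5 knots per feature, ridge-penalised logistic link.
- **discriminant**: mixture discriminant analysis — a 2-component full
  covariance Gaussian mixture per class (fewer components when a class
  is small), posterior presence probability by Bayes' rule with
  empirical priors.
- **bagged_trees**: 500 bootstrap-aggregated decision trees with default
  split parameters.
- **bioclim_envelope**: presence-only percentile envelope. Per layer the
  percentile rank p of the point among presence values uses the midpoint
  rank convention p = (n_less + 0.5 + 0.5·n_equal)/n; the layer score is
  1 − 2|p − 0.5| and the overall score the minimum over layers, hard
  zero strictly outside the observed presence range. At the extreme
  observations the score is of order 1/n rather than exactly 0.

Pseudo-absences are drawn uniformly from valid, non-presence cells of
the calibration region — in outside-envelope mode additionally
restricted to cells failing the presence surface-range envelope (tail
quantile q = 0.025 per layer, a point is inside only if within bounds on
every layer). Draws are redrawn each CV run with run-indexed seeds.

## Evaluation, filtering, committee

Partitions are stratified by class; fold sizes differ by ≤ 1. AUC uses
the Mann–Whitney rank form (ties ½). The TSS threshold scan covers
midpoints of sorted unique scores plus the two classify-all extremes
(ROC corners), so the maximum is never below 0; the smallest maximizing
threshold wins ties. The selection cutoff is mean + SD/2 (sample SD,
n−1) pooled over all records of all algorithms, applied strictly to
both metrics; an empty selection falls back to the single best-TSS
record with a logged warning.

Each selected (algorithm × run × fold) record contributes one committee
member: the model object evaluated on that fold — fitted on the fold's
75% training split — is projected and binarized at the record's own
ROC-optimal threshold. Projecting the evaluated object keeps the
threshold and the projection consistent; refitting on more data would
decouple them. Committee means are min–max normalized over valid cells
(identity when the surface already spans [0, 1]; a constant positive
surface maps to 1, constant zero to 0, preserving the unanimity
semantics).

## Stability and areas

The stability sum of the five normalized scenario surfaces is
thresholded at the 90th/95th/99th quantiles of its strictly positive
values (linear interpolation between order statistics — the convention
matters and is recorded in the run manifest). Classes are
boundary-inclusive upward (value ≥ t99 is high). Class areas count each
classified cell with weight one; scenario range areas weight each cell
by its committee average. The pooled protected share obeys the
aggregation identity Σ(area_i·pct_i)/Σ(area_i) over regions, which the
tests verify both on synthetic worlds and on published table arithmetic.
Protected overlap is computed on the rasterized (cell-center) polygon
representation, consistent with cell-level weighting; exact polygon
intersection is out of scope. Printed percentages round half-up to two
decimals, with guard digits so binary float representation cannot flip
a printed-precision tie.

## Response curves

A profile evaluates a model along one variable with all others held at
their region-wide medians (configurable to means); medians are robust
to the skewed layer distributions that remain after masking. Profiles
are smoothed by a sliding-window scheme: an OLS line per window of
w = ⌈span·n⌉ consecutive points (span 0.5, degree 1), each point's
smoothed value being the mean of predictions from all windows covering
it. The smoother is linear-invariant and reproduces exactly collinear
data; it is not classical tricube-weighted LOESS. A permutation
importance utility (mean |Δprediction| under column permutation) is
provided for ranking variables; no claim is made that it matches any
particular published importance metric.

## Determinism and provenance

One master seed fans out through named `SeedSequence` children to every
stochastic stage (climate fields, presence draws, region layout, CV
partitions, pseudo-absence draws, learner seeds), all below 2³¹. A
rerun with the same config is byte-identical, including all written
artifacts; the manifest records the derived seeds, cutoffs, selected
model counts and stability thresholds needed to re-derive any report
number.

## Known limitations

- Presence sampling bias, detection error and dispersal limits are not
  modelled; virtual-species recovery results are consistency checks.
- The committee treats all selected members equally; metric-weighted
  ensembles and spatial-block cross-validation are out of scope.
- Area accounting is raster-based; vector-exact intersections and
  ellipsoidal areas are not computed.
- The learners are idiomatic scikit-learn implementations of the five
  algorithm families, not bit-level reproductions of any other
  package's internals.
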