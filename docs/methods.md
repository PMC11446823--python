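# Methods

`localdiff` quantifies where and why high-resolution national air-pollution
models diverge from hyperlocal observations.  The analysis chain is: reduce
1 Hz mobile-monitoring streams to one long-term concentration estimate per
100 m grid cell; bring block-group-level national-model predictions and
census demographics onto the same grid; form the localized difference
LD_i = MM_i − LUR_i per cell; and model LD with Bayesian Additive
Regression Trees (BART) as a function of (a) known-local-source (KLS)
geometry densities and (b) neighborhood racial/ethnic composition.  A
synthetic-scene generator provides complete inputs with known ground truth
so that every stage is testable as a parameter-recovery problem.

## Gridding protocol

Each on-road 1 Hz point is assigned to a unique half-open 100 m cell.
Within a cell, points are partitioned into *drive passes*: maximal runs
whose consecutive time gaps do not exceed a threshold (default 60 s,
configurable — results depend on it, so it is surfaced in every config).
The cell estimate is the median of the arithmetic pass means, weighting
every visit equally regardless of dwell time; this makes the estimate
invariant to pass order and to point duplication within a pass, and bounded
by the pass-mean extremes.  Pass membership is defined per cell, so a
vehicle weaving along a cell boundary produces interleaved per-cell passes.
Cells with a single pass are retained and flagged via the `n_passes`
column; no minimum-visit filter is applied.

## Harmonization

Concentrations are intensive, so block-group predictions are resampled to
cells by area-weighted averaging of overlapping polygons.  Population is
extensive, so counts are allocated proportionally to overlap area (per
racial/ethnic group), which conserves group totals exactly when the grid
covers the block groups; per-cell shares are recomputed from allocated
counts.  Intersections are computed in projected meters (no geodesy — the
domains of interest are tens of km²); slivers below 1 m² are discarded.
The analysis set is the monitored (on-road) cells.

## KLS features

Seven source classes — residential, arterial, highway, and on-ramp roads
(polylines), food service and gas stations (points), industrial land
(polygons) — at three buffer distances (50/150/300 m from the cell edge)
give 21 predictors.  The buffer is the Euclidean dilation of the cell
square (rounded corners; "within d of the edge" is a Euclidean statement),
with closed-form area (s+2d)² − (4−π)d².  Densities are clip-length/area
(km/km²), count/area, and unioned-industrial-area/area.  The density
denominator is the buffered-region area, keeping values comparable across
buffer sizes; a fixed cell-area denominator is available as an option.  A
thin importer maps OSM-style tags (`highway=motorway_link` → on-ramp,
`amenity=restaurant|fast_food|cafe` → food service, etc.); the mapping is
explicit config because the exact upstream tag set is a free choice.

## The BART sampler

The regression is y = Σ_t g(x; T_t, M_t) + ε, ε ~ N(0, σ²), sampled by
Bayesian backfitting: each sweep proposes a structural move per tree
(grow 0.28 / prune 0.28 / change 0.44) against the partial residual of the
other trees, accepting by Metropolis–Hastings with the conjugate-normal
marginal likelihood.  Priors are the standard sum-of-trees choices:
internal-at-depth-d probability α(1+d)^(−β) with α=0.95, β=2; leaf means
N(0, σ_μ²) with σ_μ = 0.5/(k√m), k=2, on the response range-scaled to
[−0.5, 0.5]; σ² ~ scaled-inverse-χ²(ν=3, λ) with λ set so
Pr(σ² < σ̂²_LS) = q = 0.9.  Defaults m=50 trees, 250 burn-in, 1000
retained draws.  Split proposals draw a uniformly chosen eligible variable
and a uniformly chosen observed value within the leaf (strict `<` left /
`≥` right); both children must keep at least `min_leaf` = 5 observations.
The split-rule factor of the tree prior cancels the variable/cutpoint
terms of the proposal density, so acceptance ratios involve only leaf
counts, depth terms and marginal likelihoods.  A constant response
short-circuits to a degenerate intercept-only posterior.  The range
transform makes the sampler exactly shift-equivariant under a fixed seed.

Partial dependence follows Friedman: for feature j at value v, substitute
x_j = v into all n training rows and average predictions within each
posterior draw; the across-draw mean and 2.5/97.5 percentiles give the
curve and its 95% credible band.  The default evaluation grid is the
feature's 5th–95th percentiles in steps of 5, plus the exact value 0 for
zero-inflated features (most KLS columns are zero over more than half the
domain; the presence/absence contrast at zero is the quantity of
interest).  Trees that never split on j contribute a v-independent term
computed once per draw — numerically identical to the full loop, which the
tests verify to 1e-9.  Variable inclusion proportions are per-draw split
fractions averaged across draws (a splitless draw contributes uniform
1/p), so they always sum to 1.  Fit quality is pseudo-R² (1 − SSE/SST from
posterior-mean in-sample predictions) and NRMSE (RMSE divided by |ȳ|; the
absolute value applies to the mean, which is negative for NO2 LD).

## Equity analyses

Model A regresses LD on total population plus the five racial/ethnic
shares; Model B adds the 21 KLS columns.  Demographic PDPs for Model B are
evaluated on the grids frozen from Model A so the curves are numerically
comparable; the attenuation statistic is the max−min of the mean curve
restricted to the 5th–95th percentile evaluation points, reported as
range_A, range_B, difference and ratio.  A ratio below 1 indicates the
demographic LD pattern is (partly) explained by source proximity.
Population-weighted LD quartiles per group use allocated per-cell group
counts as weights, with the left-continuous inverse of the weighted ECDF
and midpoint interpolation at exact crossings — with integer weights this
reduces to ordinary quantiles of the weight-expanded sample (property-
tested).  Counts, not shares, are the weights; this follows the aggregate
"population perspective".

## Synthetic scenes

The generator emulates the statistical structure the analysis assumes:

* **Geometry.** Square 1 km² neighborhoods tiled by 100 m cells; grid-like
  residential (200 m spacing) and arterial (500 m) roads placed mid-cell;
  one east–west highway at a random height with short on-ramps; food
  service and gas stations jittered around arterials (sources co-locate
  with traffic, enabling confounding experiments); rectangular industrial
  parcels near the highway.  Sparse layers (highway, on-ramp, industrial)
  are zero over well more than half of cells, matching the regime the KLS
  features are designed for.
* **Truth surfaces.** truth = background + Σ_sources strength·exp(−d/L)
  per pollutant, each road line / point / parcel one source.  The
  exponential kernel is a deliberate simplification (only the fold-decay
  range is constrained by observation); default decay lengths L ∈
  [160, 250] m give a 2–10× excess decay between 50 m and 300 m
  (exp(250/L) ∈ [2,10] ⇔ L ∈ [250/ln 10, 250/ln 2]).  Default strengths
  and backgrounds put gridded medians near the observed regime
  (UFP ≈ 20×10³/cm³, NO2 ≈ 8 ppb on monitored cells).
* **Traces.** The fleet traverses every road once per configured pass at
  9 m/s, 1 Hz, weekdays 08:00–18:00, with leg start slots separated by
  more than any plausible gap threshold.  Measurement noise is a lognormal
  factor with median 1 drawn once per leg (temporal conditions shared
  within a visit): pass means are median-unbiased for cell truth, so the
  median-of-means estimator is asymptotically unbiased, while the
  arithmetic mean over passes is inflated by exp(sd²/2).  Defaults
  sd = 0.4 (UFP) and 0.25 (NO2); the true temporal noise magnitude is not
  observationally constrained, so these are free parameters.
* **National predictions.** Block-group means of truth regressed (OLS) on
  coarse covariates (road length, population), plus an additive bias per
  pollutant (defaults −12.4 for UFP, +0.9 ppb for NO2, emulating the
  observed substantial UFP underprediction and near-neutral NO2).  Fitted
  values of a linear smoother are smoother than truth by construction and
  miss within-block-group extremes — exactly the mechanism LD probes.
* **Demographics.** Block-group shares are Dirichlet (concentration 12
  around a Bay-Area-like base composition); the white-non-Hispanic
  concentration is tilted by exp(c·z) where z is standardized traffic-road
  density and c = demo_source_corr × 2.5, so the sign of
  `demo_source_corr` is the sign of corr(white share, source density).
  Populations are Poisson–lognormal around 1200 and independent of source
  density.

What the generator does **not** emulate: street-network routing, meteorology
and diurnal chemistry, instrument drift or inlet lag, on-road vs. ambient
offsets, spatially correlated measurement error, irregular census geography
(block groups are axis-aligned squares), and any within-block-group
population texture.  Passing recovery tests therefore demonstrates the
*estimators* are correct under the assumed structure, not that the
assumptions hold in field data.

## Problem sizes and numerical choices

Recovery tests run on 1000-cell scenes (ten neighborhoods), the scale at
which sparse-source contrasts and demographic gradients are well resolved;
the acceptance script uses the same scale with m=50 trees and 500 retained
draws.  Shorter chains (m=20–30, 100–150 burn-in, 200–300 retained) are
used for multi-seed recovery checks; experiments showed larger ensembles
slightly *worsen* PDP range recovery for correlated share predictors
(signal spreads across correlated columns — a known PDP attenuation
mechanism), so the equity recovery checks use m=30.  Geometry buffers use
32 segments per quarter circle (relative area error vs. the closed form
< 5e-4).  Ties at cell edges follow the half-open convention; split ties
use strict `<` left.  Degenerate inputs (constant response, constant
feature, zero-variance OLS predictor, all-zero weights) are flagged or
short-circuited rather than erroring mid-pipeline.

## Known limitations

* In the full synthetic study, both the national-model error and the
  racial/ethnic shares are constant within a block group, so with a few
  dozen block groups the share columns can act as implicit block-group
  identifiers: Model B may exploit them to absorb residual within-domain
  LD structure that the 21 KLS densities do not capture, and a demographic
  PDP range can then *grow* from A to B (attenuation ratio above 1) even
  though no direct demographic pathway was injected.  The attenuation
  recovery test therefore uses the controlled confounding scenario, where
  LD is constructed from a KLS column alone; the full-pipeline attenuation
  ratio is reported as a descriptive output.

* The PDP of a share predictor under correlated compositions is an
  attenuated estimand relative to the structural coefficient; recovery
  checks compare against 16·(q95−q5) with a ±25% band at the median over
  seeds for this reason.
* The sampler is single-chain; no formal convergence diagnostics are
  computed (σ² traces are exposed for inspection).
* Pooling of multiple vehicles' streams is not modeled; streams are
  treated as one fleet with non-overlapping legs.
* The national-model emulator is a linear smoother with additive bias; it
  does not reproduce model-specific artifacts (e.g. population-weighted
  internal aggregation) beyond smoothness and bias.
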