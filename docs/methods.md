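# Methods

This note documents the models implemented in `gorillaspace`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a user auditing results will want
to know.

## Spatial backbone

All stages share a planar metric grid of half-open square cells (default
500 m): cell (i, j) covers [x₀+i·s, x₀+(i+1)·s) × [y₀+j·s, y₀+(j+1)·s), so
every point maps to exactly one cell. Coordinates are assumed already
projected; no CRS handling is performed.

Herbaceous food availability per cell is energy density (kcal m⁻²): for
each species, mean predicted dry biomass over the cell's 1 m² transect
plots (an OLS calibration of dry weight on stem length or leaf count;
negative predictions clamped to zero) times its energy content (kcal g⁻¹),
summed over species. Cells without transects are *masked*, not zero, and
masked cells are excluded from choice-set candidates. The calibration is
plain OLS rather than through-origin or log-linear because per-species
functional forms vary; callers can fit their own and pass
`SpeciesCalibration` objects directly.

## Track processing

Consecutive-fix segments are split exactly at cell boundary lines by linear
interpolation, so per-cell distances sum to the polyline length (a tested
invariant at 10⁻⁶ m). Segments crossing near a four-cell corner are
assigned by midpoint cell. Cell-entry decisions are transitions in the
collapsed cell sequence; within a day, repeated (origin → chosen) pairs
count once (strictest reading of "multiple entries count as one decision";
chosen-only dedup is selectable), and a return to the day's starting cell
is included by default (`include_return_to_start`).

Two GPS-noise guards are on by default and matter in practice:

* **Blip filtering** (`drop_blips`): an interior run of a *single* fix whose
  flanking cells are identical or mutually adjacent is removed. Jitter
  flips one fix across a boundary, and a diagonal transit can clip a side
  cell with one stray fix; both fabricate spurious entry decisions (and
  convert one corner decision into two edge decisions). A genuine pass
  through a 500 m cell leaves many consecutive fixes at 30 s recording, so
  the single-fix threshold is conservative.
* **Minimum visit distance** (`UsageLedger.min_visit_distance_m`, default
  25 m): per-day track slivers below this are not counted as visits. The
  previous-use statistic divides by the day gap, so a 5 m jitter sliver
  from yesterday would otherwise masquerade as substantial recent use. A
  stationary day (a day's sole, possibly zero-distance record) is kept.

## Previous use

For group g, cell c, reference day t:
Σ over visits (g, c, d < t) of size_g(month of d)/(t − d) × distance(g, c, d),
with visits aggregated to one record per day first, so the day gap is an
integer ≥ 1 and same-day earlier passes contribute nothing. Days are
calendar-day differences. Unobserved days simply contribute nothing — with
~50% of days observed the statistic underestimates true use, which is a
property of the field design, not of the estimator. Group sizes are mean
weaned individuals per month; a missing month falls back to the group's
nearest recorded month.

## Movement-choice model

Conditional logit over choice sets (one per entry decision, 2–8 candidates).
Predictors are log(x + c) then z-scored; the shift c is half the smallest
positive value (1 if all zero), chosen so zeros stay finite without
dominating the scale. A fitted `TransformState` can be replayed on new data
so that held-out data — or a simulator's truth record — share the scale.
The log(1/n) offset cancels within sets and defines the uniform-choice null
likelihood exactly.

The likelihood is maximised by damped Newton–Raphson with analytic gradient
and Hessian (a fit at ~2000 sets takes milliseconds, which the permutation
test depends on); statsmodels' `ConditionalLogit` serves as an independent
cross-check in the test suite, not as the implementation. Separation is
flagged as non-convergence when coefficients diverge or standard errors on
the z-scale exceed 100.

The permutation full-null test reassigns each set's chosen flag to one
candidate drawn with edge/corner weights (per-candidate observed choice
frequencies, normalised within the set; user-fixable), refits, and uses the
add-one p-value (1 + #{null ≥ obs})/(1 + n_perm), default n_perm = 1000.
Predictors are never permuted; one-chosen-per-set is preserved by
construction (Gumbel-max sampling).

At the study's scale the permutation test is calibrated: 200 null
replicates of 500 sets at 200 permutations reject at 0.02–0.08 (tested).

## Utilization model

Gaussian LMM of log within-cell distance (zero-distance visits dropped — a
visit without measurable travel carries no utilization signal) on the six
within/between predictor terms plus a residual autocorrelation smoother,
with random intercepts for group, cell and group × cell. The smoother is a
Gaussian-weighted mean of the *other same-group* residuals from a fit
without the term, with weights exp(−Δt²/2σ_t²)·exp(−Δd²/2σ_s²) over day
gaps and cell-centre distances; (σ_t, σ_s) are picked from the grid
σ_t ∈ {1, 3, 7, 14, 30} d × σ_s ∈ {250, 500, 1000, 2000} m by refitted ML.
Random slopes are deliberately out of scope; inference that matters here
(the joint LRT, sign recovery) is exercised on synthetic data where the
generating model is known.

The fit is profiled maximum likelihood over the three variance ratios
γ_k = σ_k²/σ² with analytic gradient (dense Cholesky; closed-form GLS β and
σ̂² given γ), L-BFGS-B on log γ with a small multi-start so boundary fits
(σ_k² → 0) are found. At the problem sizes here (hundreds to a few thousand
rows) a fit takes well under a second, which the simulation studies
require. The engine is verified against statsmodels `MixedLM` (single
random effect, ML) to 10⁻⁴ in log-likelihood and against OLS when the
variance components vanish; in direct benchmarks on crossed designs it
reaches equal-or-better optima orders of magnitude faster than the
variance-component formula interface.

**Known small-sample property.** The LRT (2·ΔLL against χ²₆) tests three
within-group and three between-group coefficients. Between-group terms are
informed by only as many points as there are groups; with the study's 10
groups the χ² reference is anticonservative (measured type-I ≈ 0.10 at
α = 0.05 over 200 null replicates) — a property of the reference
distribution, not of the optimiser. Calibration is demonstrated at 40
groups (measured 0.06), and this small-sample behaviour is exactly why the
choice model's inference uses permutation instead. Likewise, the *sign* of
a between-group effect is only reliably determined when the effect is
large relative to its group-level standard error (|effect|/SE ≳ 3 at 10
groups); the sign-recovery experiments use −0.5 per sd accordingly.

## Kernel home ranges and overlap

Fixed-bandwidth (h = 200 m) isotropic Gaussian KDE of one location per day
(the first fix), evaluated at pixel centres on a raster padded by ≥ 4h and
normalised to mass 1. Raster resolution defaults to 50 m; halving it
changes contour areas by < 2% (tested). Percent-volume contours take
pixels in decreasing mass order until the level is reached and polygonise
the pixel union without smoothing, so areas and intersections are exactly
reproducible; captured mass lies in [level, level + max pixel mass].
Overlap per group is against the union of all other groups' polygons;
pairwise shared areas are symmetric while percentages need not be. The
area-weighted energy density of a polygon weights each unmasked cell's
value by its intersection area and divides by the polygon's area; masked
cells contribute nothing to the numerator.

Subsampling sensitivity re-estimates the 90% contour on random point
subsets per fraction and reports mean/sd; fraction 1.0 reproduces the full
estimate exactly.

## Exact Wilcoxon signed-rank test

Zeros dropped, midranks for tied |d|, T⁺ = sum of ranks of positive
differences. The exact null distribution over all 2ⁿ sign assignments is
computed by convolution on doubled (hence integer) midranks, and the
two-tailed p doubles the smaller inclusive tail, capped at 1 — the
conventional exact treatment. On the published ten-group overlap table this
gives T⁺ = 55, p = 2/1024 ≈ 0.002; the median home-range overlap is 42.025%
(printed elsewhere as 42.02) and the core median 4.26%.

## Synthetic data generator

The movement simulator reproduces the study conditions: 10 groups of 4–13
weaned individuals, a smooth positive energy landscape rescaled to
0–13 054 kcal m⁻², ~808 m of travel per day (the per-day transition count is
Poisson with rate calibrated from the expected transit and within-cell walk
lengths; the realised mean sits within ~10% of the target), multi-month
tracking with a configurable observed-day fraction (default 0.5), and
fixes every 30 s with 3 m jitter. Each transition draws the next cell from
the conditional-logit kernel with β_food = 0.5, β_self = 0.3, β_nbr = −0.3
per sd by default, plus a 2:1 edge-vs-corner bias, using the same running
`UsageLedger` the analysis uses. Within-cell travel is lognormal with a
group-level intercept and a −0.3 loading on neighbours' previous use, so
the utilization model's avoidance effect is also represented. Diagonal
transits are routed through the shared cell corner so the path never clips
the two side cells.

The generator works on fixed z-scales (food: log-z fitted on the landscape;
previous use: log(x+1) unscaled) and exports them in the truth record;
refits that aim to recover the generating coefficients should replay these
`TransformState`s, since refitting the transform on a different sample
changes the coefficient scale. Round-tripping fixes through track
processing recovers essentially all true transitions (tested ≥ 95%;
measured ~100%).

What the generator does *not* emulate: topography and movement barriers,
vegetation phenology and regrowth dynamics, demography and group fissions,
female transfer, observer effects beyond day-thinning, and GPS error beyond
isotropic jitter. Passing tests therefore demonstrate that the estimators
recover the generating process under idealised field conditions — not that
real data satisfy the models.

Two direct generators (`simulate_choice_sets`,
`simulate_utilization_rows`) draw from the exact generating models of the
choice and utilization fits; the large calibration studies (type-I error at
200 replicates) use these for speed, while the movement simulator feeds
the end-to-end recovery experiments.

**Recovery experiments** run the generator with all days observed: the
default 50% thinning is a deliberate measurement-error condition (the
ledger misses unobserved visits, attenuating the previous-use predictors),
whereas the recovery experiments concern the estimator itself. Under
sequential feedback the conditional-logit MLE shows a small away-from-zero
finite-sample deviation for the avoidance coefficient (≈ 0.7 of its
Monte-Carlo SD at ~2000 decisions); it vanishes when choices are redrawn on
frozen covariates and when the effect is zero, and the mean estimate stays
within 2 Monte-Carlo SDs of the truth, which is the tolerance the recovery
tests use (matching the ±0.15 working tolerance for β_food at that size).

## Pipeline

`run_analysis` drives everything from one config (YAML or dict): track
processing, ledger, burn-in (analysis rows before the cut-off are dropped
while the ledger keeps them as history; the default study cut-off lets the
previous-use predictors accumulate ~5 months of history), choice model with
permutation test, utilization model with scale selection and LRT, kernel
ranges, overlap report, exact tests, GeoJSON polygons and a row-count log.
All randomness flows from the config seed; rerunning a config byte-
reproduces the JSON reports (tested).

## Defaults at a glance

| parameter | default | meaning |
|---|---|---|
| cell size | 500 m | analysis grid |
| bandwidth h | 200 m | kernel UD |
| raster resolution | 50 m | UD pixels (areas converge < 2%) |
| contour levels | 0.90 / 0.50 | home range / core |
| n_perm | 1000 | permutation test |
| log shift c | half min positive | zero handling in log-z |
| σ_t grid | 1–30 d | autocorrelation day scale |
| σ_s grid | 250–2000 m | autocorrelation space scale |
| min visit distance | 25 m | ledger noise guard |
| daily travel | 808 m | simulator calibration target |
| energy max | 13 054 kcal m⁻² | simulator landscape range |
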