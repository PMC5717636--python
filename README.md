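# gorillaspace

Space-partitioning analysis for group-living, non-territorial primates —
built around the question of how mountain gorilla groups in Bwindi
Impenetrable National Park share space with their neighbours without
defending territories. The package takes GPS fix tables and vegetation
transect data to (i) daily movement-choice and utilization models on a
500 m grid and (ii) annual kernel home-range / core-area overlap statistics,
and ships a multi-group movement simulator with known coefficients so every
stage is testable without field data.

It is written for movement ecologists and spatial biostatisticians working
with grid-based step-selection designs on social species.

## The models

**Movement choice.** Each decision to enter one of the up-to-8 cells
surrounding the current 500 × 500 m cell is a choice set. With candidate
covariates x_k (herbaceous food energy density, the group's own previous use
of the cell, and the neighbours' previous use — each log- and then
z-transformed), the probability of entering cell k is the conditional logit

    P(k) = exp(x_k'β) / Σ_j exp(x_j'β),

the exact likelihood for "exactly one surrounding cell is chosen". The
log(1/n_candidates) offset is constant within a set and defines the null
model, LL₀ = Σ log(1/nᵢ). Joint significance of the predictors uses a
permutation test: each set's chosen flag is reassigned to a random
candidate, with edge-adjacent and corner-adjacent candidates weighted by
their observed overall choice frequencies, and the statistic 2·(LL − LL₀)
is recomputed per permutation.

**Previous use** of a cell by a group at a reference date is

    Σ over earlier visits of  (group size / days elapsed) × track length in cell,

in individuals·metres·day⁻¹: larger groups deplete more, elapsed time lets
vegetation regrow, and the distance travelled in a cell proxies how
intensively it was used. The neighbour version pools all other habituated
groups.

**Utilization of a chosen area.** Log distance travelled within a visited
cell is modelled by a Gaussian mixed model with each predictor split into a
within-group part (deviation from the group mean) and a between-group part
(the group mean), random intercepts for group, cell and group × cell, and a
Gaussian-kernel residual autocorrelation term over day gaps and cell-centre
distances. The six predictor terms are tested jointly by a likelihood-ratio
test (df = 6).

**Home ranges.** Fixed-kernel (h = 200 m) utilization distributions from
one location per day; home range = 90% and core area = 50% percent-volume
contour (pixel-union polygons). For group i, overlap is
100·SH_i/H_i where SH_i is the area shared with the union of all other
groups' ranges; the exclusive core is C_i − SC_i. Overlap percentages are
compared with an **exact Wilcoxon signed-rank test** (full enumeration of
the 2ⁿ sign assignments, midranks for ties).

## Worked example

`examples/` holds one short script per capability. From
`examples/03_movement_choice.py` (simulated tracks through the full
pipeline):

```
1474 choice sets from 31252 fixes
coefficient (per sd of log predictor)   estimate    truth
  food_z                               +0.418     +0.50
  prev_self_z                          +0.316     +0.30
  prev_nbr_z                           -0.204     -0.30
permutation full-null test: chi2 = 1717.51, p = 0.0020 (500 permutations)
```

The three coefficients are per-standard-deviation log-odds: positive food
and self-use terms mean groups prefer energy-rich, familiar cells; the
negative neighbour term is avoidance. The permutation p tests all
predictors jointly against uniform choice. From
`examples/05_homerange_overlap.py`, the published ten-group overlap table
gives

```
home range: median 42.03% (range 9.68-94.79)
core area : median 4.26% (range 0.0-76.09)
exact Wilcoxon signed-rank: T+ = 55, N = 10, p = 0.002
groups with core overlap below 10%: 7 of 10
```

— core areas are shared far less than home ranges: space partitioning
without territoriality.

A thin CLI wraps the pipeline: `gorillaspace simulate|analyze|study
--config cfg.yaml --seed N --out DIR`.

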