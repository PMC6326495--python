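# Methods

## The model

A landscape is a grid of cells; each conservation feature *j* (a species'
year-round, summer or winter distribution, binary presence or abundance) is
normalized to per-cell proportions `q_ji` of its full distribution, summing
to one over the habitat ("analysis") cells. Normalization makes binary and
abundance layers commensurate: a binary layer becomes a uniform weight over
occupied cells, an abundance layer weights cells by abundance. Cells outside
the analysis mask and nodata cells carry zero; a feature with no mass on the
mask is an error and must be dropped, never silently retained.

### Greedy complementarity ranking

The prioritizer removes one cell (or a batch) at a time, always the cell
whose loss costs least under the chosen objective, and the removal order —
expressed as rank fraction, last-removed = 1 — is the conservation-value
ranking of the landscape. Because `q_jn` (the proportion of feature *j*
still in the remaining set) shrinks as cells are removed, the value of a
cell depends on what has already gone: generalized complementarity.

- **Additive benefit** (`abf`): `δ_i = (1/c_i) Σ_j [(q_jn)^z − (q_jn − q_ji)^z]`.
  The concave exponent `z = 0.25` (configurable in (0, 1]) mimics a
  species–area curve: the same absolute loss costs more for a feature whose
  remaining distribution is already small, and the sum over features rewards
  richness.
- **Core-area** (`caz`): `δ_i = (1/c_i) max_j q_ji / q_jn`. A cell is as
  valuable as it is to its single most-dependent feature, which retains the
  range cores of rare, small-ranged features regardless of richness. A
  feature with `q_jn = 0` contributes ratio 0 (it no longer constrains the
  solution), avoiding 0/0.

The cost layer `c_i` defaults to 1 everywhere — ranking on biological
criteria alone — but is accepted for generality.

**Hierarchical removal masks.** Each cell carries an integer level; all
level-k cells are removed before any level-(k+1) cell, so higher levels are
guaranteed the top ranks. This is how existing protected areas are credited
(they cannot be "spent" again by the prioritization) and how the
"outside-focal" scenarios force both protected and focal areas to the top,
ranking only what lies beyond them. Within the active level, `δ_i` is still
computed against the full remaining set, levels included.

**Determinism and ties.** Ties in `δ` are broken by lowest linear cell
index. Runs are exactly reproducible; the `seed` field in the prioritizer
config is reserved and unused by the default algorithm.

**Warp.** `warp = w` removes the `w` lowest-`δ` cells per iteration using
deltas evaluated before the batch. `warp = 1` is the exact greedy algorithm
and the only setting the equivalence tests cover; larger values are a
documented approximation for large rasters.

**Numerics.** `q_jn` is recomputed from the remaining set after every
removal batch rather than updated incrementally across iterations. The
recomputation is O(features × cells), the same order as the delta sweep
itself, so it costs nothing asymptotically and keeps the ranking free of
accumulated floating-point drift — the fast path is bit-identical to the
naive reference implementation (`rank_landscape_reference`), which re-derives
everything from scratch each iteration and exists purely as a test oracle.
Negative `q_jn − q_ji` beyond 1e-9 indicates corrupted bookkeeping and
raises; values inside the tolerance are clipped to zero.

**Retained-set convention.** The "top fraction f" of a ranking is the
`floor(f·N)` best-ranked cells of the N analysis cells — equivalently the
cells with rank fraction strictly greater than 1 − f when f is a multiple of
1/N. Performance-table lookups use the largest recorded fraction ≤ f.

### Coverage evaluation

`overlap_fraction` is `Σ q_ji` over a region's cells. The random baseline is
analytic: the region's share of analysis cells, which is the exact
expectation of overlap for a feature placed uniformly at random (verified
against Monte Carlo in tests). "Better than random" is a strict inequality;
a feature exactly at baseline is not counted. Species-level tallies call a
species covered when at least one of its seasonal features is.

The equal-area comparison takes the current protection region (focal areas ∪
protected areas), reads its landscape fraction, and compares per-feature
current coverage with `coverage_at_fraction` of a rank map at that same
fraction, paired t-test on (prioritized − current). If the rank map was
built with the current region itself as the top mask level, the two
coverages coincide exactly at the masked fraction — a self-consistency
identity the tests assert to 1e-9.

`paired_t` computes `t = mean(d)/(sd(d)/√n)` with `d = x − y`, two-sided
p-value and 95% CI from the t distribution on n − 1 df (scipy supplies the
distribution; the statistic is checked against closed-form hand
computations). Zero-variance differences: identical vectors give t = 0,
p = 1 by convention; a constant non-zero difference is a degenerate-test
error because the statistic is undefined.

### Threat exposure

A threat is a boolean mask over habitat cells: either habitat forecast to
convert to a threatening land-cover class under a future scenario
(cropland, urban/mining, encroaching forest — the baseline layer only needs
to agree on the grid, since habitat membership at baseline is the analysis
mask), or invasion risk (cells classed low resistance and resilience).
Every threat applies to every feature — the working assumption is that all
habitat-associated species are affected by direct habitat loss.

Per feature, `exposure_region = Σ_{threatened} q_ji` and `exposure_focal` is
the threatened share of the feature's within-focal mass. The conditional
denominator makes the two numbers directly comparable (both are "what
proportion of the distribution in this window is at risk"); the paper-style
alternative (unconditional focal exposure) would scale with focal overlap
and confound coverage with risk. Features with zero focal mass are flagged
undefined and excluded from paired tests. Summaries report per-scenario
means, a feature-level paired test on scenario-averaged exposures
(df = features − 1) and, for multi-scenario threats, habitat-area fractions
threatened inside vs region-wide with a scenario-level paired test
(df = scenarios − 1) and means ± SE.

## The synthetic landscape generator

The generator is a statistical stand-in, not an ecological model: the
simplest construction that produces the structure the analysis assumes —
contiguous autocorrelated ranges, a nested rarity spectrum, co-distribution
with one umbrella species, focal areas that track that umbrella, and threats
that can be spatially biased relative to the focal areas.

- **Fields.** White noise convolved with an isotropic Gaussian kernel
  (`autocorr_length` cells, default 4, periodic boundaries), standardized to
  mean 0 / SD 1.
- **Species.** Field `a·U + √(1−a²)·E` (umbrella field U, independent noise
  E, association `a ∈ [−1, 1]`), thresholded at the species' range-size
  quantile. Range sizes are log-uniform on [0.01, 0.6] of the grid — a
  right-skewed spectrum with many smallish ranges and a few large ones.
  Associations default to Uniform(−0.2, 0.9): most species positively tied
  to the umbrella, a minority negative. The first three species stay
  continuous above threshold (abundance-model analogues). Ten species get
  paired summer/winter features (the winter field spatially shifted by two
  correlation lengths), 21 are summer-only, the rest year-round: 81 species,
  91 features at the defaults.
- **Masks.** The analysis mask excludes 10% of the grid via a classed
  baseline land-cover layer (forest/water/cropland/developed). Focal areas
  are the top-quantile cells of the smoothed umbrella field covering 23.3%
  of habitat (exact to one cell; ties shuffled by seed). Protected areas are
  an independent smoothed-field top quantile at 15.6%, so the expected
  focal ∪ protected union is ≈ 35.3% of habitat; overlap with focal areas is
  allowed. The 23.3%/35.3% pairing, the feature counts and the four-scenario
  layout are the study conditions the generator is built to emulate.
- **Threats.** Per scenario, a smoothed risk field plus
  `threat_bias × focal-membership` (bias in field-SD units, default −1.0:
  threats pushed away from focal areas, the empirically observed direction),
  thresholded to convert 11.5% of habitat in each of four future land-cover
  scenarios, realized as future class layers so the real `lulc_threat_mask`
  code path is exercised. Invasion risk works identically at 23.9% with the
  top cells classed low resistance/resilience.
- **Truth.** Per-feature association, range target and realized occupancy,
  per-scenario bias, and the realized focal fraction are recorded at
  generation time for recovery tests.

What the generator does *not* emulate: real species-distribution-model error
structure, habitat covariates, anisotropy, range cohesion beyond Gaussian
smoothing, partial-cell boundary rasterization, or any calibration to real
sagebrush data. Passing recovery tests therefore show the pipeline detects
planted structure of the stated kind and effect size — not that the real
system has that structure.

## Raster conventions

Grids are row-major, 0-based, origin top-left; cell *i* is `row·n_cols +
col`. All layers of one analysis must agree on shape, cell size, origin and
CRS tag (an opaque string, never interpreted); the nodata sentinel may
differ per layer (masks use 255, float layers −9999). Aggregation to a
coarser working resolution takes the block maximum, ignoring nodata
(all-nodata blocks stay nodata), with partial edge blocks allowed; the
analysis mask is built *after* aggregation, on the working grid, so every
layer lives on one grid. Candidate features are screened by a two-part
rule: keep if the distribution covers ≥ 20% of the study region
(inclusive), or if strictly more than 20% of the entire distribution lies
inside it. GeoTIFF I/O is single-band, north-up, via tifffile with the
standard ModelPixelScale/ModelTiepoint/GDAL_NODATA tags; round-trips are
bit-exact.

## Design choices where the design was open

- **Aggregate, then exclude**: the analysis mask is constructed on the
  aggregated grid (tests assert the declared order).
- **Tie-break by lowest cell index**: deterministic and oracle-friendly;
  zero-value cells (δ = 0 under both objectives) are removed first within
  their mask level, which matches the equations.
- **Strict inequality for "better than random"** and both feature- and
  species-level tallies emitted; even-sized group medians use the
  mean-of-middle convention.
- **Two-sided p-values** throughout.
- **The umbrella species itself is not a feature**: the evaluation covers
  the species under the umbrella, not the umbrella; callers may add it
  explicitly.
- **Exposure denominators** as above (conditional within focal).

## Problem sizes

Tests run on grids from 1×3 (hand-checkable oracles) to 96×96; oracle
equivalence uses 20 random stacks of ≤ 100 cells and ≤ 5 features, null
calibration 200 seeds at 48×48 with 20 species, recovery 20 seeds at 60×60
with 12 species of planted association ±0.7. The acceptance script runs the
full default conditions (96×96, 91 features) with exact greedy ranking
(warp 1) in about a minute.

## Known limitations

- The feature-level paired t-test inherits a pseudoreplication problem from
  its design: all features in one landscape are evaluated against the same
  threat realization, so their exposure differences share that realization's
  landscape-level inside-vs-outside shock. Within a landscape the test's
  "null" is false whenever the shock is non-zero, and across simulated
  landscapes with zero planted bias it rejects far above its nominal size
  (measured ≈ 31% at 5% nominal over 200 seeds). The scenario-level test
  (df = scenarios − 1) pairs independent realizations and is the better
  calibrated of the two; feature-level p-values should be read as
  descriptive. This is a property of the test design on shared spatial data,
  not of the implementation.
- Greedy ranking is O(cells² × features / warp); very large rasters need
  warp > 1, which is approximate.
- No reprojection: inputs must be pre-aligned (only block aggregation is
  provided). No connectivity/boundary-length penalties, condition layers or
  other advanced Zonation features.
- Monte-Carlo acceptance checks (recovery rates, calibration) are exact for
  the fixed seed sequences used and subject to ordinary sampling error under
  reseeding.
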