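# Methods

## Problem and model

`cumimpact` predicts how the areal cover of benthic habitats and their
associated biotopes (reefs, sandbanks, *Fucus*, *Furcellaria*, mussel
suspension feeders, *Zostera*, charophytes, higher plants) responds to
single and combined human pressures — nutrient loading, the invasive benthic
predators round goby (*Neogobius melanostomus*) and mud crab
(*Rhithropanopeus harrisii*), and offshore wind-park construction — on a
fixed 1 km² grid. The pipeline has two statistically distinct halves: a
meta-analysis that converts compiled impact-vs-reference field evidence into
habitat × pressure *sensitivity scores*, and a raster engine that applies
those scores per grid cell under a management scenario.

## Effect sizes and pooling

Each evidence record holds means, dispersions (SD or SE; SE is converted as
sd = se·√n at analysis time) and sample sizes for an impact and a reference
arm. The effect size is the response ratio RR = x̄ᵢ/x̄ᵣ, analysed as ln RR
with the delta-method sampling variance

    var(ln RR) = sdᵢ²/(nᵢ·x̄ᵢ²) + sdᵣ²/(nᵣ·x̄ᵣ²).

This is the standard choice for positive abundance/cover outcomes compared
between treatments, and the one intentional methodological reconstruction in
the package: the upstream evidence-compilation workflow states only that
effect sizes with uncertainties were computed, so we adopt the log response
ratio explicitly and document it here.

Studies sharing a habitat × pressure are pooled with DerSimonian–Laird
random effects: Cochran's Q under inverse-variance weights, the moment
estimator τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)), random-effects weights
1/(vᵢ + τ²), and a normal-theory 95 % CI (multiplier 1.96, no small-sample t
correction — scores feed a deterministic map algebra, not a hypothesis
test). With k = 1 the score is the study's own estimate and variance.
Jointly observed pressure pairs ("round goby and mud crab") are pooled as
first-class keys for the combined pressure set.

Two floors keep degenerate records usable rather than silently dropped,
each with a logged warning: a zero impact mean (total habitat destruction)
is floored at 0.001 × the reference mean before the log transform — 0.001 is
the smallest ratio observed in this literature — and var(ln RR) is floored
at 1e-8 because some digitised studies report sd = 0.

The ANOVA screen operates on the raw ratio-scale effect sizes (not ln RR),
grouped by pressure within one habitat; published decompositions for this
kind of evidence are on the ratio scale, and the screen is descriptive. The
implementation is the textbook one-way decomposition and is cross-checked in
the tests against `scipy.stats.f_oneway` on random data; pooling is
cross-checked against `statsmodels.stats.meta_analysis.combine_effects`
(`method_re="dl"`, with τ² truncated at zero, which statsmodels does not do).

Both a weighted pooled ratio and the unweighted arithmetic mean of per-study
ratios are computed (`rr_mean` and `rr_arith_mean`); the scenario engine
uses the weighted pooled value.

## Scenario algebra

A scenario is a set of active pressures with intensity layers plus a
nutrient multiplier (1.0 = business as usual; 0.75 encodes the HELCOM
Maximum-Allowable-Inputs simplification of a uniform 25 % nitrogen and
phosphorus load reduction). Per cell,

    ln RR_cell = Σₚ intensityₚ · ln RRₚ,

i.e. multiplicative combination on the ratio scale with intensity exponents.
Multiplicativity is the minimal combination rule consistent with ratio
effect sizes; where the cell's set of fully present binary pressures exactly
matches a jointly observed pressure-set key, that direct joint score
overrides the product rule (joint evidence can show a weaker combined effect
than one component alone, and does for the reef invader pair). A joint key
plus extra pressures composes the joint score with the extras; precedence is
exact match > largest joint subset + singles > product of singles. A missing
score for an active pressure raises a coverage-gap error naming the habitat
and pressure; expert-judgement scores can be merged into the matrix to fill
such gaps (flagged `evidence=expert`, never silently overriding data).

Intensity semantics per pressure type:

- **binary invaders** (round goby, mud crab): presence 0/1; exponent 1 where
  present.
- **nutrient load**: normalised concentration c with domain condition c = 1 ≡
  current load at the evidence's reference condition; the scenario multiplier
  m scales it uniformly, contributing RR^(c·m). The evidence gives no
  dose–response curve; ln-linear interpolation in c is the declared choice and
  is isolated in one place (`combined_rr`).
- **wind park**: turbine-footprint fraction f = π(d/2)²/s² of park area per
  cell (d = foundation diameter, default 100 m; s = turbine spacing, default
  800 m; f ≈ 0.0123), scaled by the cell-area fraction inside a park polygon,
  contributing RR^f.

New cover is `clip(cover · RR_cell, 0, 1)` — a cell already at 100 % cover
cannot gain. The low/mean/high maps use every pressure's rr_low/rr_mean/
rr_high respectively: bounds propagate per pressure independently, with no
cross-pressure covariance, a deliberately conservative envelope. Because all
exponents are non-negative and cover is monotone in RR, the cell-wise
ordering cover_min ≤ cover_mean ≤ cover_max is structural.

Wind parks are the one mechanism that can create habitat in a previously
empty cell (hard substrate placed on bare soft bottom). Where input cover is
0, footprint f > 0 and RR > 1, created cover = min(f·(RR − 1), f); the
footprint fraction is a hard ceiling on creation, and the rule is monotone
in RR so the min/mean/max ordering is preserved.

Impacts never propagate between cells: predictions in a cell depend only on
that cell's cover and intensities (verified as a locality property test).
Summaries count a cell as *impacted* when habitat cover > 0 and at least one
active pressure has intensity > 0 there; per-cell percent statistics
(reported to 0.1) are taken over impacted cells (computing them over all
habitat cells would dilute them with untouched cells). Totals: areal change
= Σ(cover_mean − cover_in)·1 km², and the total percent change is
100·areal/total cover rounded half away from zero to a signed integer,
matching how such summary tables are conventionally printed.

## Rasters

The analysis grain is fixed at 1000 m cells in an equal-area projected CRS,
so every cell is exactly 1 km² and areal sums are exact; geographic (degree)
rasters are rejected rather than silently reprojected. Layers are
single-band float32 GeoTIFFs written through `tifffile` with the standard
GeoTIFF georeference tags (ModelPixelScale, ModelTiepoint) and the GDAL
nodata convention; nodata is NaN in memory. Row 0 is the northernmost row;
cell (r, c) covers the half-open square [x₀+cs, x₀+(c+1)s) × (top−(r+1)s,
top−rs]. Habitat cover supplied on a 0–100 % scale is rescaled to [0, 1]
with a logged notice when the maximum exceeds 1. A NaN-aware block-mean
downsampler is provided for users whose native habitat maps are finer than
1 km (e.g. 100 m). Wind-park polygons come from GeoJSON (shapely
geometries); rasterization computes exact cell∩park area fractions.

## Synthetic data

The generators emulate the statistical shape of the real inputs, not their
geography. Evidence: per study, a study-level ratio ρᵢ = ρ·exp(σ·z) (σ
defaults to 0.5, reflecting the large between-study variance typical of this
literature), a lognormal reference mean, arm sizes n ∈ [3, 12] (small
ecological field experiments), coefficients of variation in [0.1, 0.3], and
multiplicative sampling noise of magnitude cv/√n on each arm mean — so the
delta-method variance computed downstream is an honest estimate of the
simulated sampling error. Noise is multiplicative (lognormal) throughout
because abundances are positive and the pipeline is ratio-based. A bundled
truth table mirrors the published observation counts per habitat × pressure
(19 combinations, 450 records) with true ratios set to reported group means
where available; the packaged `data/demo_evidence.csv` is one fixed-seed
draw from it, with numeric fields rounded to 3 decimals to keep the file
small.

Seascapes: habitat cover is a Gaussian random field smoothed to a configured
correlation length, pushed through its normal CDF and u^(1/μ−1) so the
expected mean cover equals the target μ; the nutrient field is a
coast-to-offshore exponential gradient with small smooth noise, normalised
to domain mean 1; invader presence thresholds a smooth field at the
(1−occupancy) quantile; wind parks are rectangles. Every generator draws
from an independent substream keyed by (seed, generator, key), so adding a
generator or key never shifts another's output.

What the synthetic data does *not* emulate: real bathymetry, salinity and
exposure gradients that structure Baltic benthic habitats; spatial
correlation between habitat and pressure layers; non-lognormal measurement
error; publication bias in the evidence base. Passing recovery tests
therefore demonstrate that the pipeline is statistically faithful to its own
model, not that the model captures every feature of field data.

## Validation and problem sizes

- Pooling: hand-computed worked example (3 studies, variances 0.01, ln RR
  −0.2/0/0.2 → Q = 8, τ² = 0.03, CI 0.797–1.254) to 1e-6; statsmodels oracle
  on random instances; exact fixed-effect reduction whenever Q ≤ k−1.
- Parameter recovery: true RR ∈ {0.384, 0.8, 1.0, 2.0} × k ∈ {3, 13, 86},
  200 replicates, σ = 0.5. At k ≥ 13 the 95 % CI covers the true ratio at
  0.90–0.96 and |bias of ln RR| < 0.05; at k = 3 coverage drops to ≈ 0.8,
  the known undercoverage of DerSimonian–Laird with z-intervals at very
  small k, and is reported but not asserted.
- Scenario invariants on 100 randomized 12×12 seascapes: CI ordering,
  range [0, 1], locality, regional additivity, and nutrient-multiplier
  monotonicity (a 0.75 multiplier never predicts less cover than 1.0 in any
  cell of any habitat with nutrient RR < 1).
- Closed forms: uniform cover with a full-occupancy binary pressure gives a
  total change of exactly 100·(RR − 1) %; the turbine footprint for
  d = 100 m, s = 800 m is π·2500/640000 ≈ 0.0123.

Grid sizes in the test-suite simulations (12×12 to 100×100) are chosen as
the smallest sizes at which the spatial statistics stabilise; the engine
itself is resolution-agnostic in cell count.

## Known limitations

- The ln-linear nutrient dose–response (RR^c) is an interpolation
  assumption, not an estimated curve.
- CI propagation ignores covariance between pressures and between cells;
  the min/max maps are envelopes, not joint confidence bands.
- No far-field effects: pressures acting beyond their own cell (e.g.
  sediment plumes, larval subsidies) are out of scope by construction.
- Pooling does not stratify by spatial vs temporal comparison mode, and no
  publication-bias diagnostics are included.
- Expert scores carry no data-derived uncertainty; their CIs are whatever
  the expert supplies.
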