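# Methods

This note documents the models, algorithms and design choices behind
`sdmpipe`, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, with which defaults,
and what the synthetic-data tests do and do not demonstrate.

## The maximum-entropy niche model

### Formulation

Given presence cells and background cells on a predictor stack, the model
is the Gibbs distribution over background cells

  q_λ(x) = exp(η(x)) / Z,  η(x) = Σ_f λ_f f(x),

with features f scaled to [0, 1] on the training data. Fitting minimises
the penalised negative log-likelihood

  J(λ) = log Σ_bg e^η − mean_pres(η) + Σ_f β_f |λ_f|,

which is convex. The per-feature penalty is
β_f = m⁻¹ᐟ² · β_mult · sched(class, m) · sd_pres(f), where m is the
presence count and `sched` is the published MaxEnt sample-size schedule per
feature class (linear/quadratic/product interpolate 1.0 → 0.05 between
m = 10 and 100; hinge constant 0.5; threshold 2.0 → 1.0; categorical
0.65 → 0.25). The presence-side standard deviation has a small floor
(0.05) so constant features are not unpenalised. `beta_multiplier`
(default 1.0) scales all penalties.

### Feature classes

* linear: (v − min)/(max − min)
* quadratic: (v² − min(v²))/(max(v²) − min(v²))
* product: pairwise v₁v₂, scaled by its own training range
* hinge: max(0, (v − knot)/(max − knot)) clipped to 1, forward hinges with
  knots at equal quantiles of the training values (default 30)
* threshold: indicator v ≥ knot, knots at equal quantiles (default 10)
* categorical: one-hot per observed integer code

Default enabled classes are linear + quadratic + hinge. Training ranges are
taken over the pooled presence + background values, so every training
feature lies in [0, 1]. Presences are reduced to one record per grid cell
before fitting (prevents pseudo-replication; duplicates of existing
presences therefore never change a fit).

### Optimizer

J(λ) is minimised by monotone FISTA: accelerated proximal-gradient steps
with soft-thresholding for the L1 term, a backtracking line search for the
local Lipschitz constant, and a momentum restart whenever a step would
increase the objective. Iteration cap 500; convergence when the relative
objective change falls below 1e-9. The tolerance is deliberately
conservative: on problems up to a few hundred features the solver then sits
within ~1e-8 of the optimum, comfortably inside the 1e-4 agreement the test
suite demands against an independent convex solver (L-BFGS-B on the split
formulation λ = a − b, a, b ≥ 0). Models that hit the iteration cap are
returned with `converged=False`; their coefficients are still the best
iterate found.

Per-iteration gain increments are attributed to features in proportion to
|Δλ_f · ∂L/∂λ_f| (equal to MaxEnt's per-iteration attribution when a single
coordinate moves), accumulated, split evenly across a product feature's two
variables, and normalised to the percent-contribution vector. Percent
importance permutes each variable's values across the pooled presence +
background records and normalises the resulting training-AUC drops to 100.

### Prediction and normalisers

After fitting, with η over the background: `linearPredictorNormalizer` is
max(η) (so the exponential never overflows on training data),
`densityNormalizer` is Σ exp(η − lpn) (so raw predictions sum to exactly 1
over the training background), and `entropy` H is the entropy of that
distribution. Outputs: raw (density), cloglog 1 − exp(−e^H·raw) (default,
the MaxEnt 3.4+ convention) and logistic e^H·raw/(1 + e^H·raw). Both 0–1
transforms are monotone in raw, so rank-based statistics (AUC, Boyce,
Spearman niche recovery) are identical under either; stored products use
cloglog × 100 on the percent scale. When projecting, predictors are clamped
to their training ranges by default and the fraction of cells touched by
clamping is recorded on each map — extrapolation is routine for
late-century scenarios and should be visible, not silent.

### Lambdas text format

One line per feature — `name, λ, min, max` — where the name encodes the
transform (`bio01`, `bio01^2`, `bio01*bio02`, `'bio01` for a hinge whose
min field is the knot, `(12.5<bio01)` for a threshold, `(region=3)` for a
categorical level), followed by `linearPredictorNormalizer`,
`densityNormalizer`, `numBackgroundPoints` and `entropy` lines. A linear
line is always emitted for every continuous variable (λ = 0 if unused) so
the file carries every training range; reading a written file reproduces
the model bit-exactly (floats serialised with `%.17g`).

## Validation

**AUC** is the Mann–Whitney statistic of presence scores over background
scores (ties 0.5), computed from mid-ranks. Cross-validation shuffles
presences into k = 10 folds differing in size by at most one, fits on k−1
folds, scores the held-out fold against the background, and reports the
per-fold and mean AUC; the final model is refit on all presences. With
fewer presences than folds, k is reduced with a warning.

**Continuous Boyce Index.** All scores are first mapped through the
landscape empirical CDF; 101 windows of width 0.1 (in cumulative
probability) slide over [0, 1]; per window P is the fraction of presences
and E the fraction of landscape cells inside; windows with E = 0 are
dropped and the index is the Spearman correlation (mid-ranks) of P/E
against the window midpoint. Working on the rank scale makes the index
exactly invariant under any strictly monotone rescaling of the suitability
axis — the property that motivates the index — where fixed-width windows
on the raw score range would only be approximately so. Degenerate inputs
(all presence scores equal, or constant P/E) return NaN rather than a
number.

**Quality flags** classify each species against the conventional
thresholds — AUC > 0.7 and Boyce > 0.5 — into pass_both / auc_only /
boyce_only / fail_both. Per-species reports are written as
`maxentResults.csv` (per-fold + mean AUC) and `boyce_index_score.csv`.

**Variable selection** is codified as explicit rules because the original
procedure mixes statistics with expert judgement: a variable is retained
iff (mean percent contribution ≥ 0.5 OR mean percent importance ≥ 0.5) AND
(complexity class "simple" OR whitelisted on ecological grounds; BIO15
seeds the default whitelist as the one complex climate variable retained in
published practice). The shipped test fixture combines the published means
for the 18 retained variables with synthetic sub-threshold rows for the 17
screened-out candidates, and the default rules reproduce the 35 → 18 cut.

## Projection, interpolation and ensembles

Projection applies a lambdas model to every (scenario, gcm, period) stack
plus the historical stack, producing percent-scale maps. A missing stack
can be filled by per-cell linear interpolation in time between the nearest
bracketing periods of the same scenario and GCM (the historical stack may
serve as the early bracket; categorical layers carry the earlier period's
codes since class codes cannot be averaged). Interpolated values are convex
combinations of the brackets by construction. The historical anchor year is
1990.

Ensembling takes the per-cell min / mean / max across the (default 8) GCMs
of each scenario × period, computed on the transformed percent-scale maps —
matching how ensemble products are actually deposited and read — rather
than on raw densities. The historical period carries a single (mean) map;
with S scenarios, P future periods and 3 statistics each species yields
1 + S·P·3 rasters, which at the published scale (10,633 species, 4
scenarios, 4 future periods) is 521,017.

## Geospatial summaries

Suitability maps are resampled 5 km → 1 km by value-preserving subdivision
(each cell becomes a 5 × 5 block of identical 1-km cells): the per-cell
value is a quality weight, not a density, so subdivision — not smoothing —
conserves the quality-weighted sum exactly. qwHA is then Σp over valid
cells of the unit-scale 1-km map, in km².

The change map is computed as p_future − p_hist by default, so positive
values mark improving areas, with a flag (`as_printed`) for the opposite
orientation; the refugia map is p_hist·p_future/100 on the percent scale,
bounded by min(p_hist, p_future), symmetric in its arguments. Per-species
summary tables report qwHA and absolute/proportional change versus the
historical area per scenario × period × ensemble statistic; a zero
historical area flags proportional change as NaN (undefined, never
infinite). Consolidation concatenates species tables and bins
ensemble-mean proportional changes at 10-percentage-point width for
change-distribution histograms.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical shape* of the real inputs:

* **Landscape.** 19 bioclimatic-like + 15 soil-like continuous layers plus
  1 categorical region layer = 35 candidate predictors on a 5-km grid.
  Continuous layers are Gaussian-kernel-smoothed white noise (correlation
  length in cells, default 4) plus a deterministic north–south gradient;
  temperature-like layers are in °C around 20, precipitation-like layers
  are positive (mm, log-normal-like) so multiplicative drying keeps them
  physical; the region layer is a nearest-seed (Voronoi) partition. An
  optional contiguous "ocean" nodata mask can be carved.
* **Climate futures.** Scenarios carry severity weights (default 0.25 /
  0.5 / 0.75 / 1.0 across the four standard RCP-SSP combinations);
  temperature-like layers drift additively (default 4 °C at the most
  severe scenario's final period), precipitation-like layers
  multiplicatively (default −30%), both scaled by severity × time
  progress; each GCM perturbs the drift with one fixed jitter draw per
  layer (sd 0.15), so a GCM is consistently warm or cool. Soil and region
  layers are time-invariant. Default grid: 4 scenarios × 8 GCMs × 4 future
  periods (2030–2090) over a 1990 baseline.
* **Species and records.** Virtual species have known suitability
  functions (Gaussian/logistic responses combined by product or weighted
  geometric mean, always in [0, 1]); occurrences are drawn with cell
  probability ∝ suitability × optional bias surface (a "roadside"
  accessibility gradient is provided); target-group backgrounds pool a
  group's occurrences and subsample 10,000 points without replacement,
  matching how survey bias is carried into the background. Default
  occurrence count is 123 per species (the published median).

Everything is deterministic under its seed, byte-identically.

Not emulated: real spatial covariance structure between specific
bioclimatic variables, occurrence-record cleaning protocols, true CMIP6
downscaling, dispersal, or land use. Consequently, passing tests show the
*pipeline machinery* is correct (fitting recovers known niches, metrics
match their definitions, projections and summaries follow their equations)
— they do not certify predictive skill on real species data.

### The niche-recovery harness

The recovery benchmark fixes a 40 × 40 landscape (seed 7), draws 20
replicate Gaussian-niche species (optima at quantiles 0.3–0.7 of a
temperature and a precipitation layer, widths 0.5–1.5 × the layer sd),
samples 200 presences each, fits with default features against all valid
cells as background, and requires Spearman(true, predicted) ≥ 0.9 in at
least 18 of 20 seeds. The final fit uses the species' niche predictors —
the set the variable-selection stage supplies when the niche is known.
Fitting against all 35 candidate layers instead degrades recovery to
ρ ≈ 0.8–0.9, not through optimizer error (fits are converged and oracle-
checked) but because spurious coefficients on correlated candidate layers
absorb sampling noise — the overfitting-by-predictor-excess effect that
motivates variable selection in the first place.

### Small-group caveat for target-group backgrounds

With only a handful of similar virtual species per group, the pooled
background nearly coincides with the presences and AUC collapses towards
0.5 while landscape-referenced Boyce stays high — the known degeneracy of
target-group backgrounds for small or narrow groups. Demo defaults
therefore spread niche optima widely, and a `background_mode="landscape"`
alternative (uniform valid cells) is available.

## Problem sizes and determinism

Test-scale defaults (40 × 40 grids, 16 × 16 for the end-to-end smoke run,
backgrounds of 120–1,000 points, 3–5 species) are distinct from the
published scale and are the sizes the shipped test suite runs at; the
paper-scale configuration drives the output manifest only. All stage seeds
are derived arithmetically from the single config seed; identical configs
produce byte-identical tabular outputs. Raster products are float32 TIFFs
(LZW) with JSON sidecars; tabular products are plain CSV.

## Known limitations

* The optimizer is dense: feature matrices of ~10⁵ background cells ×
  ~10³ features fit comfortably, but continental 5-km grids should be
  fitted on background samples (as MaxEnt itself does), not on every cell.
* Percent contribution for full-gradient steps is an attribution heuristic;
  it matches MaxEnt's definition exactly only in the single-coordinate
  limit.
* Hinge knots use equal quantiles rather than MaxEnt's exact (undocumented)
  knot rule; coefficients are therefore not line-for-line comparable with
  Java MaxEnt lambdas files, though the format is.
* The Boyce window scheme (ECDF-scale windows) is one of several in use;
  absolute index values can differ slightly from raw-scale-window
  implementations on heavily tied score distributions.
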