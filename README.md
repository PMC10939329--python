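# sdmpipe

A tested, reusable pipeline for continental-scale habitat-suitability
modelling under climate change: presence-background maximum-entropy (MaxEnt)
niche models fitted on environmental raster stacks, validated with AUC and
the continuous Boyce Index, projected across a climate-scenario × GCM ×
time-period grid, ensembled across GCMs, and summarised as quality-weighted
habitat area, change maps and climate-refugia maps.

It is aimed at spatial ecologists and conservation modellers who need the
whole workflow — from predictor stack to per-species data products — to be
reproducible and testable without multi-gigabyte occurrence and climate
downloads. A first-class synthetic-data module generates landscapes,
scenario-graded climate futures and *virtual species* with known niches, so
every stage (including niche recovery) can be verified end to end.

## The model

MaxEnt estimates a species' relative environmental suitability from
presence-only records and background (pseudo-absence) points. Over
background cells *x* it fits the Gibbs distribution

```
q_λ(x) ∝ exp( Σ_f λ_f f(x) )
```

where the features *f* are transforms of the predictors (linear, quadratic,
product, hinge, threshold, categorical) scaled to [0, 1], and the
coefficients λ maximise the L1-penalised log-likelihood of the presences

```
L(λ) = mean_presences(η) − log Σ_background e^η − Σ_f β_f |λ_f| ,   η(x) = Σ_f λ_f f(x).
```

This is a concave problem; `sdmpipe` solves it with a monotone accelerated
proximal-gradient method and checks itself against a generic convex
optimizer in its test suite. Fitted models serialise to the plain-text
*lambdas* format (feature name, λ, min, max per line plus normalisation
constants), which is sufficient to re-project the model onto any predictor
stack — including future climate stacks, with predictors clamped to their
training ranges. Raw densities are mapped to a 0–1 suitability index via
the cloglog (default) or logistic transform, and stored products use the
0–100 percent scale.

Downstream raster algebra, per species *t*, period *y*, scenario *c*
(suitability *p* on the percent scale, maps resampled to 1 km):

* quality-weighted habitat area `qwHA = Σ_cells p` (km²; a 1-km cell at
  suitability 0.3 contributes 0.3 km²),
* change map `S = p_future − p_hist` (positive = improving),
* refugia map `r = p_hist · p_future / 100` (high where suitable in both
  periods).

Ensembles across GCMs take the per-cell minimum, mean and maximum.

## Worked example

Fit and validate a virtual species with a known Gaussian niche, project it
under all four scenarios and eight GCMs, and summarise habitat area:

```python
import numpy as np
import sdmpipe as s
from sdmpipe.synthetic import landscape_background

stack = s.make_landscape(s.LandscapeSpec(grid_rows=40, grid_cols=40, seed=7))
temp, rain = stack.layer("bio01"), stack.layer("bio12")
species = s.VirtualSpecies(
    "demo_sp", "mammal",
    niche={"bio01": s.GaussianResponse(float(np.quantile(temp, 0.4)), float(temp.std() * 0.7)),
           "bio12": s.GaussianResponse(float(np.quantile(rain, 0.6)), float(rain.std()))})
occ = s.sample_occurrences(species, stack, n=200, seed=1)
bg = landscape_background(stack, sample_size=1000, seed=2)

report, model = s.crossvalidate(occ, bg, stack, s.FeatureConfig(), k=10, seed=3)
print(f"mean test AUC : {report.mean_auc:.3f}")
print(f"Boyce Index   : {report.boyce:.3f}")

stacks = s.make_future_stacks(stack, s.ScenarioSpec(seed=4))
cube = s.ensemble_stats(s.project_all(model, stacks, stack))
table = s.summarize_species(cube)
hist = table[table.scenario == "historical"].iloc[0]
worst = table[(table.scenario == "RCP8.5-SSP5") & (table.period == 2090)
              & (table.stat == "mean")].iloc[0]
print(f"historical qwHA        : {hist.qwha_km2:,.0f} km2")
print(f"RCP8.5-SSP5 2090 qwHA  : {worst.qwha_km2:,.0f} km2 ({worst.delta_prop:+.1%})")
```

which prints:

```
mean test AUC : 0.697
Boyce Index   : 0.983
historical qwHA        : 16,820 km2
RCP8.5-SSP5 2090 qwHA  : 8,792 km2 (-47.7%)
```

The Boyce Index near 1 shows presences concentrate monotonically in
high-suitability cells; the modest AUC reflects that this demo species is
widespread on a small landscape (AUC is prevalence-dependent), not a poor
model. Habitat area roughly halves by 2090 under the most severe scenario
because the species' thermal optimum sits below the drifted temperatures.

The full workflow — synthetic inputs, target-group backgrounds, per-species
folders with `maxentResults.csv`, `boyce_index_score.csv` and lambdas
files, ensemble maps and consolidated qwHA tables — runs from one YAML
config via the CLI:

```
sdmpipe run-all --config config.yaml
sdmpipe manifest --scale paper
```

`manifest --scale paper` enumerates the full published-scale data product
(10,633 species × 49 maps each = 521,017 rasters) without computing any of
them.

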