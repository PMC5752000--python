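# nichecomp

Quantifying interspecific competition between sympatric small mammals —
a generalist rodent (Keen's mouse, *Peromyscus keeni*) and an insectivore
(dusky shrew, *Sorex monticolus*) — from live-trapping, habitat, isotope
and metabolic data.  The package implements the full inference chain of a
robust-design field study as tested, reusable code, and ships a synthetic
data generator with known ground truth so every estimator can be validated
end to end.

## What it computes

**Abundance and density.**  Marked mice are estimated per grid × primary
session with a closed-population constant-detection model (M0): with *n*
observed individuals, *d* total detections over *T* occasions, the
profile likelihood over population size *N* is

    L(N) ∝ [N!/(N−n)!] p̂^d (1−p̂)^(E(N)−d),   p̂ = d / E(N),

with exposure E(N) censored at trap death; 95 % intervals come from the
χ²₁ profile cutoff.  Unmarked shrews use a dead-and-alive
Horvitz–Thompson procedure: N̂ = n_live/p* + n_dead, with p* the
per-session detection probability supplied by configuration.  Densities
divide N̂ by the effective trapping area (trap rectangle buffered by 50 m
or by half the mean maximum distance moved, MMDM).

**Competition coefficients.**  Shrew density (standardized to mean 0,
sd 1 within year) is regressed on standardized mouse density and habitat
covariates; the slope on mouse density is the dimensionless competition
coefficient α.  Fifteen regressive and sixteen auto-regressive candidate
models (the latter always carrying the previous-session shrew term) are
ranked by AICc; among models with ΔAICc ≤ 2 the most parsimonious is
selected.

**Diet and niche.**  Consumer (δ¹³C, δ¹⁵N) values are inverted through a
concentration-dependent dual-isotope mixing model — for each element
δ_mix = Σᵢ pᵢ cᵢ δᵢ / Σᵢ pᵢ cᵢ after diet–tissue discrimination
correction — with unique 3-source solutions or the mean ± SD over the
feasible polytope for ≥ 4 sources.  Dietary overlap applies the > 20 %
criterion per item; group differences use a K-nearest-neighbor
randomization test.  Isotopic niches are 50/75/95 % probability-mass
contours of a kernel utilization density, with areas (‰²) and directed
overlap percentages.

**Community energetics.**  Session-3 abundances times per-individual
field metabolic rates (mass-scaled for shrews) give habitat × year energy
totals; compensation ratios (percent of a reference year's total) test
the zero-sum expectation under competitive release.

## Worked example

Simulate one year of a 21-grid study with a planted competition
coefficient of −0.9, then fit the auto-regressive candidate set on the
standardized truth:

```python
from nichecomp.simulate import SimConfig, simulate_dynamics, truth_regression_table
from nichecomp.competition import CompetitionModel

cfg = SimConfig(n_grids=21, n_years=1, alpha_true=-0.9, noise_sd=0.3, seed=1)
state = simulate_dynamics(cfg)
tbl = truth_regression_table(state, year=0)
print(CompetitionModel(tbl, autoregressive=True).fit().summary(max_rows=4))
```

```
Competition model selection (auto-regressive set, 16 models, n = 42)
                                        model  k   AICc  dAICc    R2  alpha  selected
            shrew ~ shrew_lag + mouse_density  4 28.965  0.000 0.911 -0.947      True
    shrew ~ shrew_lag + mouse_density + nmds2  5 29.803  0.838 0.915 -0.951     False
shrew ~ shrew_lag + mouse_density + elevation  5 30.567  1.602 0.913 -0.956     False
    shrew ~ shrew_lag + mouse_density + nmds1  5 31.162  2.197 0.912 -0.953     False
selected: shrew ~ shrew_lag + mouse_density
alpha (effect of mice on shrews): -0.947
```

The selected model recovers the generating configuration (lag + mouse
density) and an α̂ of −0.947 against the planted −0.9; the ΔAICc ≤ 2 set
contains only models carrying the mouse term.  Abundance estimation works
the same way:

```python
import numpy as np
from nichecomp import abundance as ab

rng = np.random.default_rng(1)
det = (rng.random((100, 5)) < 0.3).astype(int)   # truth: N = 100, p = 0.3
det = det[det.sum(axis=1) > 0]
print(ab.ClosedPopulationM0(ab.CaptureMatrix(det, 5)).fit().summary())
```

```
Closed-population M0 abundance
  individuals observed : 88
  occasions (T)        : 5
  total detections     : 159
  N-hat                : 104.73
  p-hat (per occasion) : 0.3036
  95% profile interval : (95.07, 119.10)
  log-likelihood       : 31.444
```

The full pipeline (simulate → abundance → competition → diet → niche →
energetics) runs from the shell:

```sh
nichecomp run-all --out run/ --seed 1
```

writing `density.csv`, `competition_table.csv`, `diet_table.csv`,
`niche_table.csv`, `energy_table.csv`, `run.log` and a machine-readable
`summary.json`.

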