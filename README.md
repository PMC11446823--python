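# localdiff

**Localized difference between national air-pollution model predictions and
hyperlocal mobile-monitoring observations.**

National land-use-regression (LUR) models predict long-term NO2 and
ultrafine-particle (UFP) concentrations at census block-group resolution
across whole countries.  Mobile monitoring — instrumented vehicles logging
1 Hz concentrations while driving every street — resolves the same
pollutants at 100 m scale and reveals near-source peaks that regression
models smooth away.  `localdiff` implements the full analysis chain for
quantifying and explaining that divergence:

1. **Gridding** (`localdiff.gridding`): reduce 1 Hz streams to one
   long-term estimate per 0.01 km² cell — isolate per-cell *drive passes*
   by time gaps, average within a pass, take the median of pass means.
2. **Harmonization** (`localdiff.harmonize`): resample block-group
   predictions to the grid by area-weighted averaging, allocate census
   population counts conservatively, and form the *localized difference*

   LD_i = MM_i − LUR_i

   per cell *i* (positive LD = the national model underpredicts locally).
3. **Known-local-source features** (`localdiff.features`): 21 predictors —
   road density by class (residential / arterial / highway / on-ramp),
   food-service and gas-station density, industrial land share — within
   50 / 150 / 300 m of each cell's edge.
4. **Inference** (`localdiff.bart`): a from-scratch Bayesian Additive
   Regression Trees sampler,

   LD = Σ_{t=1..m} g(x; T_t, M_t) + ε,  ε ~ N(0, σ²),

   with backfitting MCMC, Friedman partial-dependence curves carrying 95%
   posterior credible bands, variable-inclusion proportions, pseudo-R² and
   NRMSE.
5. **Equity analysis** (`localdiff.equity`): population-weighted LD
   distributions by racial/ethnic group; Model A (LD ~ population + five
   shares) vs. Model B (+ 21 KLS columns), and the attenuation of
   demographic partial-dependence curves between them — the probe for
   whether demographic exposure-misclassification patterns are explained
   by source proximity.

A synthetic-scene generator (`localdiff.scene`) produces complete study
inputs — road networks, point and polygon sources, ground-truth surfaces
with exponential near-source decay, block groups with correlated
demographics, biased smooth "national model" predictions, and simulated
drive traces — so every stage is testable as a parameter-recovery problem.
See `docs/methods.md` for the model details and assumptions.

## Worked example

Fit BART to a synthetic localized difference driven by highway presence
(`LD = 10·I(highway within 150 m) + N(0, 2)`, 1000 cells) and read off the
presence/absence partial-dependence step:

```python
import numpy as np
from localdiff.bart import BART, BartConfig
from localdiff.features import synthetic_kls_matrix

kls = synthetic_kls_matrix(1000, seed=4)
rng = np.random.default_rng(42)
x = kls["KLS_highway_150"].to_numpy()
ld = 10.0 * (x > 0) + rng.normal(0, 2, len(x))

res = BART(ld, kls, config=BartConfig(n_trees=20, n_burn=100, n_post=200, seed=4)).fit()
print(res.summary())

pdp = res.partial_dependence("KLS_highway_150",
                             eval_values=[0.0, float(np.median(x[x > 0]))])
step = pdp.draws[1] - pdp.draws[0]
print("presence step: %.2f  95%% CI [%.2f, %.2f]"
      % (step.mean(), *np.percentile(step, [2.5, 97.5])))
```

```
Sum-of-trees regression (BART) results
==============================================
Observations:                             1000
Predictors:                                 21
Trees:                                      20
Retained draws:                            200
Burn-in:                                   100
Pseudo-R2:                               0.803
NRMSE:                                   1.091
sigma (post. mean):                      2.019
sigma 95% CI:                   [1.919, 2.136]
----------------------------------------------
Top variables by inclusion proportion:
  KLS_highway_150                      0.216
  KLS_highway_300                      0.114
  ...

presence step: 10.42  95% CI [9.52, 11.35]
```

The sampler recovers the injected effect (10) inside its credible band,
ranks the causal column first by inclusion proportion, and its σ posterior
(2.02) matches the injected noise.

## Pipeline CLI

The staged pipeline (with manifests, hashing and up-to-date detection) is
exposed as a console script:

```sh
localdiff run-all --seed 1 --out ld_out          # or stage by stage:
localdiff simulate --seed 1 --out ld_out
localdiff grid     --out ld_out
localdiff features --out ld_out
localdiff harmonize --out ld_out
localdiff fit-kls  --out ld_out
localdiff fit-demo --out ld_out
localdiff report   --out ld_out
```

Outputs are plain GeoJSON/CSV/JSON: the tidy per-cell record table
(`cells.csv`), VIP and PDP tables per pollutant, the Model A/B attenuation
report, population-weighted LD summaries, and the OLS comparison of MM
against LUR.

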