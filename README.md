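# extropt

Response-surface and neural-surrogate modelling, with genetic-algorithm
optimization, of an ultrasound-assisted aqueous two-phase extraction
(UAATPE) of *Cornus officinalis* fruit polysaccharides.

The package is written for process-optimization and chemometrics work: it
re-implements, as tested reusable code, the complete computational pipeline
of a published four-factor extraction study — Box-Behnken design,
quadratic response-surface methodology (RSM) with full ANOVA, a 4-10-1
feedforward artificial neural network (ANN) metamodel, a six-metric
RSM-vs-ANN comparison, and binary genetic-algorithm (GA) maximization of
the ANN surrogate. The study's printed 30-run design table and network
parameters ship as packaged fixtures, so every published number that can be
recomputed from printed data is recomputed here.

## The model

The extraction yield *Y* (%) is modelled over four factors — ultrasound
power *X*₁ (200–400 W), temperature *X*₂ (50–70 °C), liquid-to-solid ratio
*X*₃ (15–25 mL/g), time *X*₄ (20–40 min) — in coded units (low/centre/high
→ −1/0/+1):

* **RSM**: the full second-order polynomial
  *Y* = β₀ + Σβⱼ*X*ⱼ + Σβⱼⱼ*X*ⱼ² + Σᵢ<ⱼβᵢⱼ*X*ᵢ*X*ⱼ + *e*,
  fitted by OLS on the 30-run Box-Behnken design (24 edge runs + 6 centre
  replicates), with partial-SS ANOVA, lack-of-fit test against pure error,
  and refitting after removal of terms with *p* > 0.05.
* **ANN**: inputs and response min-max scaled to [−1, 1], one
  tansig hidden layer (tansig(x) = 2/(1+e^(−2x))−1), linear output;
  trained by Levenberg–Marquardt with validation-based early stopping.
* **GA**: 5 bits per factor (20-bit chromosomes, 32 levels per axis),
  roulette selection, two-point crossover (p = 0.8), per-bit mutation
  (p = 0.05), elitism 1, 70 generations, maximizing the ANN surrogate.
* **Metrics**: R², MSE, RMSE, SSE (two conventions), AIC = n ln(SSE)+2p,
  and AAD% for any predicted/observed pair.

A synthetic-data generator (`extropt.synth`) draws Box-Behnken datasets
from a known quadratic (optionally non-quadratic) truth with Gaussian
replicate noise, so every stage is testable against exact ground truth.

## Worked example

```python
import numpy as np
from extropt import rsm, ann, ga
from extropt.design import load_table1

table = load_table1()                      # the packaged 30-run design
full = rsm.fit_quadratic(table)
report = rsm.anova(full, table)
print(round(report.R2, 4), round(report.R2_adj, 4))   # 0.8906 0.7885
reduced = rsm.reduce_model(full, table, alpha=0.05)
print(round(reduced.intercept, 2))                    # 7.34

weights, scalers = ann.load_fixture_weights()          # published network
result = ga.run_ga(lambda x: float(ann.forward(weights, scalers, x)[0]),
                   ga.GAConfig(seed=0, max_generations=70))
print(np.round(result.best_actual, 2), round(result.best_fitness, 3))
# [400.    50.    17.26  40.  ] 8.096
print(ga.practical_round(result.best_actual, np.array(ga.PAPER_INCREMENTS),
                         ga.PAPER_BOUNDS))
# [400.  50.  17.  40.]
```

The first numbers are the study's ANOVA headline (89.06 % of yield
variance explained; adjusted 78.85 %) and the reduced model's intercept,
i.e. the predicted yield at the centre point. The GA lines maximize the
*shipped reference network* over the factor box and snap the optimum to
equipment-achievable settings. Note the reference network's optimum
differs from the published one: the shipped parameter block carries an
exact Nguyen–Widrow initialization signature and does not reproduce the
published predictions — see `docs/methods.md` for the full analysis.

The same pipeline is available as numbered drivers (`analysis/01_…` to
`05_…`), as a CLI (`extropt run`, `extropt fit-rsm design.csv`,
`extropt optimize weights.json`, …), and as a single library call
(`extropt.run_pipeline()`).

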