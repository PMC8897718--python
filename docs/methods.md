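# Methods

This note records the modelling choices, numerical conventions, and known
limitations of the package. It is the authoritative account of *why* the
code does what it does; the README shows *how* to run it.

## Design construction and coding

A Box-Behnken design for k factors consists of 4·C(k,2) edge runs — every
factor pair at (±1, ±1) with all other factors at centre — plus replicated
centre runs. `build_bbd` emits edge runs in factor-pair lexicographic
order with centres last. The physical experiment is randomized in time;
run order never enters any computation here, so a deterministic order is
kept (it makes fixtures diffable). Coded and actual units are linked by
the affine map x_coded = (x − centre)/halfwidth; both are stored to full
precision and ±1/0 receive no special casing. The packaged 30-run table
uses 6 centre replicates, the count visible in the shipped data (the
study text never states it).

Design CSVs carry actual units with header
`run,X1_power_W,X2_temp_C,X3_ratio_mL_per_g,X4_time_min,yield_pct`; an
empty response cell means "not yet measured". When factor ranges are not
supplied to `read_design`, they are inferred from column extremes, which
is exact for any design that exercises its full range (as a BBD does).

## Response-surface fit and ANOVA

The full quadratic (15 terms for k = 4) is fitted by ordinary least
squares in coded units. Per-term tests use partial (drop-one, "Type III")
sums of squares, F = SS_term / MS_residual; on this near-orthogonal BBD
these match the single-df rows that DOE software prints. The residual is
split into pure error (squared deviations within replicate groups, i.e.
the 6 centre runs) and lack of fit; their mean-square ratio tests model
adequacy. CV% is defined as 100·√MS_residual / mean(y).

Reduction at α (default 0.05) refits with only the terms whose partial-F
p ≤ α, intercept always kept, **ties retained** (the study's reduced model
keeps the time term at p = 0.0484, and a ≤ comparison is what preserves a
term sitting exactly at α). Hierarchy is deliberately not enforced: the
published reduced model keeps X₁X₄ and X₁² while dropping linear X₁, and
this package reproduces exactly that nine-term set.

Verification against the published ANOVA: R² = 0.8906, adjusted R² =
0.7885, model F = 8.72, pure-error SS = 0.078, lack-of-fit F = 0.11, and
the per-term F values all reproduce at printed precision, with two
documented exceptions:

* the published liquid-to-solid-ratio F (11.74) disagrees with its own
  printed SS/MS (0.072/0.006285 = 11.47); we compute 11.47, consistent
  with the printed SS and p = 0.0041 — the 11.74 appears to be a digit
  transposition;
* the published CV = 0.7595 is not derivable from the printed mean
  squares under the standard definition above (we compute 1.109). The
  computed value is reported as-is rather than calibrated toward the
  printed one, since the published formula is unstated.

## Neural metamodel

Architecture: k inputs → H tansig hidden neurons → 1 linear output, with
every variable (inputs *and* response) min-max normalized to [−1, 1] from
the data extremes, predictions denormalized after the output layer. For
the packaged design the input extremes coincide with the declared factor
ranges, so normalized inputs equal coded units.

Training is Levenberg–Marquardt on the normalized training subset: solve
(JᵀJ + μI)δ = −Jᵀr with the analytic Jacobian of the network output;
rejected steps multiply μ by 10 and retry, accepted steps multiply by 0.1,
μ overflow (10¹⁰) stops training. The recorded training MSE is therefore
non-increasing by construction. Data are split 80/10/10 by a seeded
random permutation into contiguous blocks; the study's own split is
unrecoverable, so its training-trace numbers (best validation MSE
0.055394 at epoch 7, the per-subset R values) are seed-dependent and are
documented, not asserted. Early stopping uses patience 10 (the study's
stated validation-failure count), returning the weights of the
best-validation epoch. Weights initialize uniformly in [−0.5, 0.5] from
the seeded generator — simple and reproducible; Nguyen–Widrow
initialization is not claimed by the study text and is not implemented.

### The shipped reference weights are an initialization, not a trained net

The published 10×4 input-weight matrix, 10-vector biases and output layer
ship verbatim in `extropt/data/ann_weights.json`, read row-major as 10×4
(rows = hidden neurons, the orientation matching the published statement
that the input-to-hidden matrix is 10×4). Two structural facts identify
this block as a Nguyen–Widrow *initial* state rather than trained
parameters:

* all ten rows of the input matrix have the same Euclidean norm, 2.4896,
  to printed precision;
* the hidden-bias magnitudes form an exact arithmetic ladder (0.276621,
  0.829864, 1.383106, 1.936349, 2.48959; common difference 0.553243),
  symmetric about the midpoint, with the top rung equal to the common row
  norm.

Both properties are how MATLAB's `initnw` lays out a fresh layer and are
destroyed by any Levenberg–Marquardt step. Consistently, no reading of
the printed block (row/column-major, either transpose, reversed rows or
columns, reversed bias/output vectors, any input permutation, [0, 1]
scaling variants) reproduces the published predictions: the best
achievable MSE over the 30 runs is ≈ 0.10 versus the published 0.0018,
and the best prediction-observation correlation is 0.56 versus the
published R = 0.976. Under the canonical reading the network predicts
7.845 % at the published optimum coordinates (published prediction:
7.66 %) and MSE 0.2212 over the design.

The package therefore treats the shipped block as what it verifiably is:
a deterministic reference function, useful for GA/grid equivalence checks
and for exercising the fixture path, whose outputs are reported as
computed. The acceptance suite asserts the published 7.66 / 0.0018 values
at their printed precision and those two checks fail honestly; no
calibration, substitution, or tolerance-widening is applied. Also note
the printed bias vector is *not* perfectly antisymmetric — the two outer
magnitude pairs repeat with equal sign — so fixture integrity is checked
via magnitude symmetry, which holds exactly.

## Metric suite

R², MSE, RMSE are standard. SSE is computed under two conventions — the
study's printed definition with a 1/n² prefactor (so SSE = MSE/n) and the
field-standard plain sum of squares — because the published SSE values
(0.0266 and 0.1515) are inconsistent with the published MSE values under
either reading. Both are always reported; the default label follows the
study's definition. AIC = n·ln(SSE) + 2p uses the selected SSE; p is the
active-term count (intercept included) for polynomial models and the full
weight-plus-bias count for networks (61 for 4-10-1) — the study never
defines p, so the choice is explicit and configurable. AAD% places
observed values in the denominator. The published RSM-side comparison
metrics (R² 0.8253, MSE 0.0101) cannot be reconciled with the study's own
ANOVA decomposition on any point set we can construct; the package
computes metrics for both the full and reduced polynomial over all 30
runs and reports them as computed.

## Genetic algorithm

Binary coding with 5 bits per factor. The study's chromosome-length
arithmetic is self-contradictory ("30 equal parts", substring length 5,
total length 30 for 4 factors); the operative statement is 5 bits per
variable, giving 20-bit chromosomes and 32 levels per axis mapped linearly
onto [low, high] (both bounds representable). Fitness-proportional
roulette selection requires positive weights, so a floor shift
(f − min + ε) is applied automatically when needed. Two-point crossover
swaps the segment between two distinct cut indices, *inclusive of both* —
the convention is stated because off-by-one variants abound. Elitism
(default 1) carries the best chromosome unchanged, making the recorded
best-fitness history non-decreasing; set 0 for a strict reading of the
study, which never mentions elitism. Stopping: 70 generations (the
study's run length) or 20 stall generations without 10⁻⁶ improvement.
Because the decodable set is a finite 32⁴ grid, exhaustive grid search is
a feasible oracle, and the tests require the GA (best of 10 seeds) to
come within 10⁻³ of the true grid maximum. Equipment rounding snaps each
coordinate to its achievable increment (50 W, 1 °C, 1 mL/g, 1 min),
halfway cases away from zero, clipped to the box.

The published raw optimum (355.49 W, 50.914 °C, …) lies on no 31- or
32-level grid, consistent with the study having used a real-coded GA
implementation; our binary GA can only be compared against its own
decodable set, which is what the oracle-equivalence check does.

## Synthetic data generator

`paper_like_spec` draws Box-Behnken datasets whose truth is the published
reduced polynomial with i.i.d. Gaussian replicate noise. Noise levels:
0.125 yield points is the data-derived value (the sample SD of the six
packaged centre yields, √(0.0777/5)); 0.08 is a named low-noise setting
for recovery studies. The generator emulates the homoscedastic-Gaussian,
smooth-surface assumption of the whole pipeline and nothing else: no
run-order drift, no heteroscedasticity, no outliers — so passing recovery
tests demonstrate correctness of the estimators under the assumed model,
not robustness to real-data pathologies. An optional tanh ridge
(`tansig_bump`) makes the truth non-quadratic, which is the regime where
the network surrogate genuinely beats the quadratic fit; on a purely
quadratic truth the polynomial is correctly specified and the comparison
is uninformative. Ground-truth box optima are located by a 21-point
coarse grid per axis with three local refinements, ample for the smooth
surfaces generated here.

## Problem sizes and determinism

Everything runs on one CPU in seconds to a few minutes: the design has 30
runs, networks have ≤ 61 parameters, the GA evaluates 20 × 71 points per
run, grid oracles enumerate 32⁴ ≈ 10⁶ points vectorized, and Monte-Carlo
recovery studies use 200 replicate datasets. All stochastic stages
(training splits and initialization, GA, generator noise) consume a
single integer seed through numpy's `default_rng`; repeated runs with the
same seed are bit-identical, and the pipeline report serializes to
byte-identical JSON.

## Known limitations

* Single response variable; no desirability-based multi-response
  optimization, no canonical/ridge analysis of the stationary point.
* One hidden layer and tansig/linear transfer only; no regularization or
  Bayesian training.
* The GA is the plain binary textbook variant the study describes:
  roulette + two-point crossover + bit mutation; no tournament selection,
  adaptive rates, or real coding.
* The shipped reference network cannot reproduce the published
  predictions for the structural reasons above; published values that
  depend on the authors' actual trained network or their random split
  (validation trace, per-subset R, ANN-side metrics, the 7.66 % optimum
  prediction) are reproducible only qualitatively, via freshly trained
  surrogates.
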