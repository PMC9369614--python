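# Methods

## Designs and coding

Factors are handled on the coded scale, `actual = center + step × coded`.
The Box–Behnken factors default to the experimental ranges of the study:
temperature 60 ± 10 °C, ethanol 60 ± 20 %, ultrasonic power 225 ± 25 W.
New Plackett–Burman layouts come from the standard cyclic 12-run generator;
the screening table bundled as `table1_pbd.csv` is the *printed* matrix,
kept verbatim because its row/column assignment does not match any obvious
permutation of the standard generator. Coded points outside [−1, 1] decode
with a warning rather than an error, because optimizers legitimately return
fractional codes.

A note on the screening fixture: refitting the printed screening matrix does
not reproduce the first-order equation published alongside it (the printed
responses have grand mean 5.0692 against a published intercept of 5.0680,
and the strongest coefficient refits to ≈0.26 against a published 0.6033).
The two are mutually inconsistent as printed, so no test asserts the
published screening coefficients; the estimator is validated by planted-
effect recovery, ranking recovery under noise, and a type-I-error simulation
instead.

## Screening model

Ordinary least squares of the run means on the ±1 columns. On an orthogonal
two-level design the intercept is the grand mean and each coefficient is
half the difference of level means; both identities are tested. The
standardized effect is the |t| statistic of the coefficient, and the Pareto
threshold is the two-sided t critical value at α = 0.05 on the residual
degrees of freedom (runs − factors − 1 = 3 here, supplied by the dummy
columns). Replicate SDs are carried but not used as weights — the source
tables give no replicate-level data to support weighting.

## Response surface and ANOVA

The 10-term quadratic is fitted by least squares in coded units;
R² = SS(model)/SS(total). ANOVA follows the convention that reproduces
every row of the published table simultaneously:

* per-term SS are partial (drop-one) SS;
* group SS (linear, quadratic, cross-product) are drop-group partial SS.

At Box–Behnken points the linear and cross columns are mutually orthogonal,
so the three group SS partition SS(model) exactly and the linear/cross
per-term SS sum to their groups. The pure-quadratic columns are correlated
with the intercept and one another, so their per-term SS deliberately do
*not* sum to the quadratic group SS — the published table has the same
property and the suite asserts it rather than "fixing" it. Pure error comes
from exactly replicated coded runs (the three centre points, df = 2);
lack-of-fit is the remainder of the residual, tested against pure error.
p-values are upper-tail F probabilities.

Fitting uses the printed 2-decimal response means; the published fit used
unrounded data, so small drift (e.g. R² 0.9756 vs 0.9751, error SS 0.0582 vs
0.0596) is expected and covered by the stated tolerances.

### Diagnostics

Internally studentized residuals are reported for the normal-probability
plot. Outlier *flags*, however, use the externally (deletion) studentized
residuals against the Bonferroni limit t(0.05/2n, n−p−1): the internal form
is bounded by √(n−p) = 2.24 for this design, so a gross outlier could never
cross a fixed threshold of 3. With the deletion form the published fit shows
zero flags while a planted +1 mg/g corruption is caught (its mirror edge run
can be dragged over the limit too; the tests allow that).

### Polynomial optimum

The stationary point is solved analytically and polished with bounded
quasi-Newton restarts from a 3³ lattice, which handles boundary maxima of
indefinite surfaces; agreement with a 0.001-resolution grid search is a
test invariant (≤1e−3 in position, ≤1e−6 in value).

## Surrogate network

Architecture 3–h–1: tanh hidden layer, affine output; inputs mapped to
[−1, 1] by the design's ranges, output standardized. Training is
Levenberg–Marquardt on the training-subset residuals with analytic
Jacobian: damping starts at 1e−3, ×10 on a rejected step, ÷10 on an
accepted one, at most 1000 epochs. The 15 runs split 11/2/2
(train/validation/test) by largest-remainder rounding of the 70/15/15
fractions, reshuffled per seed. Early stopping halts after six consecutive
epochs without a validation improvement and returns the weights of the best
validation epoch — taken over *trained* epochs only, never the random
initial net. Initialization is Nguyen–Widrow for the hidden layer with
small (σ = 0.1) random output weights, so the initial function is smooth
and the early LM epochs fit broad trends before fine structure.

The degree of approximation scores a trained net as
`Da = c / [(n_c/n)·RMSE_c + (n_t/n)·RMSE_t + |RMSE_c − RMSE_t|]` with c = 3,
where the calibration set is the training subset (n_c = 11) and the test
set is validation ∪ test (n_t = 4). Larger is better; the |difference|
term penalizes widths that overfit the calibration runs. Width selection
takes the median Da over seeds, ties to the smaller width.

### What a 15-run surrogate can and cannot do

With 11 training points and two validation points, restart quality is
intrinsically noisy: the validation subset is too small to reliably select
a good early-stopping epoch. Across random restarts the median overall
correlation between surrogate predictions and all 15 observations is ≈0.85,
with the best restarts reaching ≈0.98. For calibration: even the *true*
10-term quadratic refit to 11-run training subsets has a median overall
correlation of 0.94 across splits — so a median of 0.98 across restarts is
not attainable by any honestly early-stopped surrogate of this size, and a
single published 0.98 should be read as a favourable draw. The GA-maximized
*prediction*, by contrast, is robust across restarts (median ≈6.26–6.31
mg/g), because many different nets agree about where the surface is highest.

## Genetic algorithm

Real-coded, single population of 20 over the coded box: rank-scaled
stochastic-uniform selection, 2 elites, scattered (per-gene uniform)
crossover on 80% of the non-elite offspring, gaussian mutation on the rest
with scale shrinking linearly from 0.2 to 0.02 of the box width, clipping
to bounds after every operator. The run minimizes the negative objective,
so recorded fitness decreases; elitism makes best fitness monotone. It
stops at 100 generations or after 50 generations without improvement
beyond 1e−8. Migration parameters are accepted for config fidelity but are
no-ops in a single-population run. Non-finite objective values are assigned
the generation's worst fitness rather than aborting.

## Kinetics

Second-order solid–liquid model `dC/dt = k (Cs − C)²`, integrated from
C(0) = 0 to `C(t) = Cs²kt/(1 + Cs·k·t)`. The linearized fit regresses t/C
on t (Cs = 1/slope, k = slope²/intercept), excluding C = 0 points; the
nonlinear fit solves the same model in concentration space, initialized
from the linearized estimates. Both are exact on model-true data (a test
identity). Under noise they differ; both are reported. A nonpositive slope
or intercept rejects the linearization as inapplicable — with multiplicative
noise this happens occasionally when the true intercept is small (the
ultrasound parameters give 1/(k·Cs²) ≈ 0.076), so Monte-Carlo summaries are
taken over the applicable replicates. Rate constants are weakly identified
when sampling starts near saturation; saturated concentrations are robust.

## Assays

Rutin calibration is an OLS line of absorbance on concentration (slope must
be positive). The yield chain divides out the calibration, multiplies by
the reaction/aliquot dilution (10 mL / 0.2 mL by default, times any extra
dilution), and scales by extract volume over sample mass (10 mL / 0.5 g).
Scavenging percent is `(1 − (A_sample − A_background)/A_control) × 100`,
clamped above at 100; the source never prints its formula, so the universal
convention for these assays is used for all three (DPPH, ABTS, hydroxyl).

## Synthetic data

The generators default to the study's own conditions: the published
quadratic coefficients with gaussian replicate noise of sd 0.05 mg/g
(the magnitude of the printed replicate SDs, 0.03–0.35); first-order
screening truths on the Plackett–Burman layout; kinetics from the
integrated second-order form at Cs = 6.31 mg/g, k = 0.33 (ultrasound) and
Cs = 4.76, k = 0.11 (reflux) on a 5–60 min grid with 2% multiplicative
noise (colorimetric error scales with concentration); assay absorbances
inverted exactly from planted yields and scavenging percentages. Every
generator is deterministic under a fixed seed, and every noiseless
generator composed with its estimator is the identity on parameters.

What the generators do not emulate: real replicate structure (only run
means are modelled), systematic drift between runs, deviations from the
quadratic/second-order model forms, and assay interferences. Passing
recovery tests therefore demonstrates estimator correctness under the
assumed models, not robustness to model misspecification.

## Problem sizes

All analyses run on the 12- and 15-run published tables. Monte-Carlo
checks use 200 replicates (kinetics recovery, assay bias), 500 (surface
coefficient unbiasedness), and 600–2000 (screening type-I error); the
surrogate/GA medians use 10–20 restarts. These sizes give Monte-Carlo
standard errors well inside the asserted tolerances.

## Known limitations

* The screening fixture cannot reproduce its published equation (see above);
  screening correctness rests on synthetic recovery.
* Published kinetics R² values (0.9985/0.9994) are not reproducible because
  the raw time-courses were never tabulated; synthetic stand-ins are used.
* The Da-vs-width trace is noisy at n = 15 and need not select the published
  width 10; the headline surrogate results fix width 10 directly.
* IC50/EC50 estimation and general reaction orders n ≠ 2 are out of scope.
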