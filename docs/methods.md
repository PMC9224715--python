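# Methods

## The problem

Clinical gait laboratories measure the 2-minute walk test (2MWT) — the
distance in meters a patient walks in two minutes — with a staff-guided
odometer. Body-worn inertial sensor systems already produce dozens of
aggregated spatiotemporal gait parameters per patient (cadence, gait speed,
stride length, swing and support phases, arm motion, per side and averaged).
`gaitffdb` trains a feed-forward network to predict the measured 2MWT
distance from such a feature table, and — more importantly — optimizes that
network through a *transparent, recoverable* staged benchmark rather than a
black-box hyperparameter tuner, so that every configuration decision can be
traced, reproduced, and explained to clinical stakeholders.

## Quality metric

For one configuration, `n_exp` independent experiments are run; each draws a
fresh 80/20 train/validation split and a fresh weight initialization. With
`RMSE_e` the validation root-mean-square error (meters) of experiment `e`
and `dist_avg` the mean measured distance of the full cohort:

    MSEarr = (1/n_exp) * sum_e RMSE_e / dist_avg

The division by one global `dist_avg` (not per-split means) makes scores
dimensionless and comparable across cohorts; `MSEarr = 0.061` reads as "the
typical prediction error is 6.1% of the average walking distance". The SD of
`RMSE_e / dist_avg` across experiments accompanies every score, because
single runs of small networks on small cohorts are volatile. A configuration
in which more than half of the experiments diverge (non-finite loss) is
scored at the ceiling `MSEarr = 1` — an error as large as the quantity being
predicted — rather than excluded silently.

## The staged benchmark

The configuration space has four axes: training algorithm (SGD, RMSProp,
Adam, Adadelta, Adagrad, Adamax, Nadam), learning rate, hidden-layer width
factor (*spread*: hidden width = round(spread x input dimension)), and
hidden-layer count (*depth*). A full factorial at the default grids —
`estimate_space(10, 50, 6, 6, 7) = 126,000` training runs — is beyond desk
scale, so the benchmark walks a fixed fraction in four stages, freezing one
axis per stage:

1. **Epoch calibration.** Every algorithm trains once at a small probe
   learning rate (1e-4, below each optimizer's customary default) and the
   mid-size shape. The per-epoch loss histories and a plateau flag (relative
   improvement over the final 10% of epochs < 1%) document that the epoch
   budget (default 1000) is generous; the budget is deliberately *not*
   adapted — changing it per algorithm would re-entangle it with the
   learning rate.
2. **Learning-rate sweep.** Per algorithm, `c_lr` (default 50) rates
   logarithmically equispaced in [1e-6, 1e-1], endpoints included, at the
   mid-size shape (spread 3, depth 3); each point scored by `MSEarr` over
   `n_exp` experiments. The per-algorithm optimum is the minimum of the
   window-3 moving-averaged curve — raw curves are noisy, and a single lucky
   run should not pick the rate. Ties go to the smaller rate. The moving
   average is centered and shrinks its window at the series edges, so output
   length equals input length.
3. **Shape grid.** Per algorithm at its optimal rate, all spread x depth
   combinations (default 1..6 x 1..6), recording both the score matrix and
   the SD matrix. Ties prefer the smaller spread, then the smaller depth —
   the smaller model is the conservative choice.
4. **Final comparison.** Fresh `n_exp` experiments per algorithm at its
   optimized configuration; the minimum-score algorithm wins (ties resolve
   by the plan's algorithm order). The winner's aggregated
   validation predictions feed the error-distribution summary (< 15 m /
   15–25 m / > 25 m absolute error), the reliability analysis, and the
   reverse-weight sanity check.

Every training run's stage, configuration, derived seed, and outcome is
logged in the report, and the per-stage run counts equal closed-form
functions of the plan — the run log is the audit trail that makes any stage
independently re-executable.

### Seeding

A master seed derives one seed per (stage, algorithm, configuration,
experiment) through `numpy.random.SeedSequence`, and each run splits that
into a data-split seed and a network seed. Experiments therefore re-draw
both the split and the initialization, never share state across stages, and
the whole benchmark is bit-reproducible from the master seed on a fixed
numerical backend.

## The regressor

A fully connected feed-forward network: input dimension → (hidden width) x
depth → 1 linear output neuron predicting meters. Hidden activation is ReLU
and the output is linear (the conventional regression defaults); weights are
Glorot-uniform initialized, biases zero. Training minimizes mean squared
error with mini-batches of 32 (seed-controlled shuffling). Optimizer
hyperparameters other than the learning rate stay at the framework-customary
defaults (momenta 0.9/0.999, rho 0.9 or 0.95, epsilon 1e-7, Adagrad
accumulator 0.1): the benchmark tunes the learning rate only, by design.

The target is never normalized — the network regresses meters directly, so
every reported error is in meters and relative errors use the raw cohort
mean. Features, by contrast, are z-scored (below).

### Numerical implementation

Parameters are float32 (as is customary for this model class) and live in
one contiguous vector; weight matrices are views into it, and the optimizers
update the vector in place through preallocated scratch buffers. Per-sample
squared errors are accumulated in float64 and summed in patient order, so
the reported epoch loss is independent of the batch partition. Moment
accumulators of dead units decay geometrically into the float32 denormal
range, which stalls the CPU by orders of magnitude; accumulator entries
below 1e-30 are therefore flushed to exact zero every 100 steps (the flush
is deterministic and far below any meaningful moment scale). A run that
produces a non-finite epoch loss or non-finite weights is marked failed and
scored by the failed-run policy; it never raises.

## Preprocessing

Fitted on training rows only, applied unchanged to validation rows — the
fit/apply separation is the leakage guard, and permuting or corrupting
validation rows cannot change the fitted model. Order of operations:

1. **Imputation:** missing cells take the per-feature mean of the observed
   training entries.
2. **Outlier treatment:** winsorization at mean ± k·SD (default k = 4) of
   the observed training entries. Clipping rather than dropping preserves
   the cohort size; sensor glitches become boundary values instead of lost
   patients.
3. **Standardization:** z-scoring with the center/scale of the
   imputed-and-clipped training matrix (population SD, ddof = 0; constant
   features get scale 1).

The 80/20 split rounds the training size half away from zero (500 patients
→ exactly 400/100) and is a seeded permutation.

## Reverse-weight feature impact

The sanity check asks whether the trained model attends to plausible
features. Each input feature receives a signed score by backward
propagation of pure synapse weights: the output neuron starts at 1, and a
neuron's score is the width-averaged weighted sum of its outgoing synapses'
scores,

    score_i(l) = (1/width(l+1)) * sum_j W[i,j] * score_j(l+1).

Equivalently, a feature's score is the sum over all input→output paths of
the product of path weights, scaled by the product of 1/width over traversed
layers; for an all-linear network it is exactly the input gradient times a
constant. Biases and activations are deliberately ignored — the score
reflects the wiring, not a local linearization at a data point — and signs
are kept, so features can carry negative scores. Scores are averaged over
the winner's ensemble (one model per final-stage experiment) to smooth
initialization noise, then ranked; the top-5/bottom-5 excerpt is the
human-facing check. The score is *not* a calibrated importance measure (no
permutation or gradient attribution); it is a cheap transparency probe, and
is documented as such.

## Reliability

Agreement between measured and predicted distances is quantified by the
intraclass correlation coefficient in its two-way random-effects,
absolute-agreement, single-measure form, ICC(2,1) — the standard form for
method comparison, treating the odometer measurement and the model as two
raters of every patient. It is computed from the two-way ANOVA mean squares
with the McGraw–Wong F-based 95% confidence interval; perfect agreement
returns 1 with a degenerate interval, and constant input (zero
between-patient variance) is an error rather than a number. Per-patient
absolute (m) and relative differences are reported as absolute values with
mean ± SD (sample SD, ddof = 1).

## Synthetic cohorts

The clinical data behind this class of study are not public, so the
generator emulates their statistical shape for testing and demonstration:

- One latent walking-ability factor per patient; the measured distance is
  `dist_center + dist_spread * latent` (defaults 137 m / 33 m, matching the
  cohort scale of published 2MWT studies in multiple sclerosis) with
  multiplicative noise of relative SD `noise_rel` (default 0.05), truncated
  positive.
- A small informative set (default 5 of 92 features) are affine functions of
  the latent factor with cadence-, speed- and stride-like units and scales;
  their own noise defaults to `noise_rel`, so a fully noiseless spec makes
  the distance an exact function of each informative feature.
- The remaining features are correlated nuisance: rank-5 shared factors,
  independent of the latent, explaining ~98% of each feature's variance,
  with a 15% idiosyncratic SD. This mirrors two properties of aggregated
  sensor tables: columns are per-patient means over on the order of a
  hundred gait cycles, so within-patient noise is a small fraction of
  between-patient variance (published within-session reliabilities for such
  parameters are ICC ≈ 0.95–0.98), and the left/right/aggregate columns of
  a few dozen underlying quantities are heavily mutually redundant. The
  idiosyncratic share matters: were the 87 nuisance columns closer to
  independent unit-variance noise, an unregularized network interpolating
  400 training patients would carry an irreducible ~10% validation error
  regardless of configuration, which is not how redundant sensor tables
  behave.
- Missing cells (default 2%) and gross outliers (default 0.5%, ±8 feature
  SDs) are injected uniformly at random.

What the generator does **not** emulate: nonlinear feature–distance
relationships, disability-dependent subgroup structure, informative
missingness, or any biomechanics. Passing recovery tests on these cohorts
shows the pipeline finds planted linear-latent signal under realistic
redundancy and noise; it does not certify clinical accuracy on real
patients. Recovery quality is epoch-hungry at this cohort size: at 150
epochs the same plan lands visibly short of its 200-epoch scores, which is
why the scaled-down reference plan fixes 200 epochs.

## Problem sizes used in the test suite and acceptance script

Exercising the full default plan (126,000 runs) is intentionally out of
scope for tests. The suite's end-to-end scenarios use 500-patient cohorts
with two algorithms (Adam, Adadelta), 6–10 learning-rate points, shapes
{1,3,5} x {1,3,5}, 3 experiments per configuration, and 200–300 epochs; the
acceptance script runs the same scaled-down reference plan. These sizes
preserve every structural property of the full design
(stage order, seeding, selection, accounting) at a few hundred training
runs. Determinism is verified on a further reduced plan, since
bit-reproducibility is scale-independent.

## Known limitations

- Feature selection, redundancy analysis, and optimizer-specific
  hyperparameters beyond the learning rate are out of scope by design.
- `MSEarr` averages RMSEs across experiments; it does not separate bias
  from variance, and the failed-run ceiling makes diverging and merely bad
  configurations indistinguishable at the top of the scale.
- The reverse-weight score ignores activations; for deep ReLU networks it
  is a wiring summary, not an attribution method, and strongly correlated
  features share credit arbitrarily.
- Single-network predictions are volatile across seeds (the reported SDs
  quantify this); the fitted searcher therefore predicts with the ensemble
  mean of the winner's models.
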