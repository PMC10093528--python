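# Methods

## Problem and scope

`fnnsweep` quantifies how the tunable hyperparameters of a fully connected
feedforward neural network (FNN) affect held-out prediction performance and
overfitting in binary clinical-outcome prediction — the concrete setting is
5-year breast-cancer-metastasis prediction from tabular EHR features. The
package implements the complete empirical protocol: a from-scratch FNN
trainer exposing exactly eleven hyperparameters, stratified 5-fold
cross-validation scored by ROC AUC, a relative train/test AUC gap statistic,
repeated one-at-a-time and paired grid sweeps, and range-based
hyperparameter ranking. Because the original EHR cohort cannot be bundled, a
synthetic-data module generates cohorts of the same shape with a *known*
ground-truth risk model, which makes model capacity, signal recovery and
overfitting directly measurable.

## The network and its eleven hyperparameters

The model is an FNN with ReLU hidden activations and a single output unit
passed through either the logistic sigmoid or its piecewise-linear
approximation, the hard sigmoid `clip(0.2x + 0.5, 0, 1)`. Training minimizes
mean binary cross-entropy plus optional weight penalties

    L = BCE(y, p) + l1 * Σ|W| + l2 * Σ W²    (biases exempt)

by mini-batch SGD with classical momentum and an iteration-based
learning-rate decay:

    lr_t = lr₀ / (1 + decay · t),   v ← m·v − lr_t·g,   w ← w + v.

The eleven tunables, with their defaults (the protocol's base values):

| hyperparameter     | default        | notes |
|--------------------|----------------|-------|
| output activation  | sigmoid        | or hard_sigmoid |
| weight initializer | glorot_normal  | five schemes, see below |
| hidden layers      | 2              | width 75 each (configurable) |
| learning rate      | 0.005          | lr₀ above |
| momentum           | 0.9            | classical (not Nesterov) |
| decay              | 0.01           | per mini-batch update by default |
| dropout rate       | 0.5            | inverted, hidden layers only |
| epochs             | 100            | full passes over the training fold |
| batch size         | 10             | clamped to the fold size if larger |
| L1                 | 0              | lasso-style sparsity penalty |
| L2                 | 0.008          | ridge-style weight decay |

Initializer scales: glorot_normal `N(0, √(2/(fan_in+fan_out)))`,
glorot_uniform `U(±√(6/(fan_in+fan_out)))`, lecun_uniform `U(±√(3/fan_in))`,
plain uniform `U(±0.05)` and plain normal `N(0, 0.05)`.

Design choices where the design was genuinely open:

- **Loss.** Binary cross-entropy with one sigmoid/hard-sigmoid output unit —
  the standard pairing for a binary endpoint. A two-unit softmax output is
  mathematically equivalent and not separately implemented.
- **Decay counter.** `t` counts completed mini-batch updates by default
  (the convention of the legacy Keras SGD optimizer);
  `decay_mode="epoch"` switches to per-epoch counting. Both are exposed
  because reasonable implementations differ, and the choice materially
  changes how fast the step size collapses on long runs.
- **Dropout.** Inverted (kept units rescaled by 1/(1−rate) at train time),
  applied to hidden-layer outputs only; inputs are never dropped.
- **Numerical guards.** Probabilities are clipped to [1e-7, 1−1e-7] inside
  the cross-entropy; the backward pass propagates zero gradient through the
  clip, so analytic gradients agree with finite differences even at
  saturated outputs. A non-finite loss or gradient raises a divergence
  error naming the epoch rather than silently producing NaN weights.
- **Determinism.** `train` is a pure function of (data, hyperparameters,
  seed): initialization, the per-epoch shuffle and the dropout masks all
  draw from one seeded generator.

## Evaluation

AUC is computed by the Mann–Whitney identity with midranks (ties count
1/2), O(n log n) via a single ranking; it is exactly the probability that a
random positive case outscores a random negative one. Cross-validation is
stratified: within each class, cases are shuffled (seeded) and dealt
round-robin into 5 folds, so each fold's class counts are within ±1 of
n_class/5. One network is trained per held-out fold, with fold sub-seed
`seed·1000 + fold`. Training AUC is computed on the concatenated four
training folds after training finishes.

Overfitting is summarized by

    percent_AUC_diff = (mean_train_AUC − mean_test_AUC) / mean_test_AUC

over the five folds, flagged when it exceeds a threshold (default 5%,
configurable). The statistic can be negative when test happens to beat
train.

## The sweep protocol

A single-hyperparameter sweep gives a range of values to one hyperparameter
while the other ten each hold a single value, and repeats the whole grid
`n_reps` times (30 in the full protocol). Two modes are provided for the
held hyperparameters, because the protocol admits both readings:
`randomized` (default) draws one value per repetition per hyperparameter
from its tested value set, seeded per (hyperparameter, repetition);
`fixed` keeps all ten at base values. Reported per-value metrics are means
over repetitions ("means of means"). Per-hyperparameter sensitivity is the
**range**: the mean over repetitions of the per-repetition maximum of a
metric, minus the mean of the per-repetition minimum. Hyperparameters are
ranked by descending range; ties break alphabetically.

Grid values are materialized by index arithmetic — `start + i·step` rounded
to the step's decimal precision — never by floating-point accumulation, so
`0.1 + 3·0.1` is exactly `0.4` and every grid reproduces its printed count
(learning rate 400, momentum 9, epochs 80, batch size 838 at step 5, L1
501, L2 701; the decay range 0–0.2 at step 0.0005 yields 401 points by the
closed form). Paired (interactive) sweeps evaluate the cross-product of two
grids with the remaining nine hyperparameters at base values.

Every (repetition, grid value) work unit derives its seed from the master
seed, the hyperparameter index, the repetition and the value index only, so
results are independent of execution order and bit-reproducible.

## The synthetic cohort generator

The generator emulates a breast-cancer-metastasis EHR table: by default
4189 cases × 31 features (10 binary, 6 ordinal 0–3, 15 standardized
continuous), an event prevalence of 0.25 (a plausible 5-year metastasis
rate; the original cohort's prevalence is not published, and nothing
downstream depends on the default), 6 signal features carrying log-odds
effects of alternating sign plus 2 pairwise interaction terms, and the
remaining features pure noise. Labels are Bernoulli draws from
`sigmoid(truth)`, where the intercept is solved by bisection so the mean
event probability matches the requested prevalence.

The *structural* randomness (per-column distribution parameters, which
columns carry signal, effect sizes, interaction pairs) comes from a fixed
internal generator, while the per-case draws use the user's seed. The
ground-truth log-odds (`bayes_scores`) therefore have a Bayes AUC that is a
property of the configuration, not of the seed, and `target_bayes_auc`
can calibrate the effect scale by bisection against a Monte-Carlo AUC
estimate (n = 50 000, fixed internal seed); calibration lands within ±0.02
of targets in [0.6, 0.8] at n = 20 000.

What the generator does **not** emulate: the real cohort's feature
semantics and correlation structure, missing-data patterns, measurement
error, or temporal structure. Passing tests on synthetic cohorts
demonstrate that the machinery measures what it claims (signal recovery,
inducible overfitting, correct bookkeeping), not that any clinical finding
transfers to real EHR data.

## Problem sizes used in tests and the acceptance script

The full protocol (4189 cases, 30 repetitions, grids up to 838 values)
is a cluster-scale computation. The package's own experiments are run
scaled down, as is standard for a reference implementation: the
qualitative overfitting checks use an 800-case cohort with 6 signal
features and Bayes AUC calibrated to 0.75 (a realistic ceiling for
metastasis prediction from clinical features), an epochs grid
{10, 50, 250, 1000} × 3 repetitions at fixed base values, and an L2
contrast {0, 0.1} at 60 epochs. At these sizes the epochs sweep reproduces
the expected picture — training AUC non-decreasing in epochs and a larger
train/test gap at 1000 than at 10 epochs — and L2 = 0.1 roughly halves
percent_AUC_diff relative to L2 = 0. Numeric values at these scales are
not comparable to the full-scale study figures and are not meant to be.

## Known limitations

- Single CPU, dense NumPy; the per-update cost of batch-size-10 SGD
  dominates long runs. Sweeps at published scale are out of reach here by
  design; the protocol code is identical either way.
- The L1 subgradient uses `sign(W)` with `sign(0) = 0`; finite-difference
  validation is performed away from zero weights, kinks and clip
  boundaries, where the loss is differentiable.
- `stratified_kfold` requires ≥ k members per class; degenerate cohorts
  are rejected rather than silently splittable.
- Adagrad, Nesterov momentum, early stopping and multi-class outputs are
  deliberately out of scope.
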