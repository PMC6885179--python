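# Methods

## Model

The classifier is an ensemble of `P` LSTM networks over fixed-length
multivariate daily series. One base learner is a single-layer LSTM block
(forget/input/output gates, cell memory; matrices act on the concatenation
`[h_{t−1}, X_t]`) unrolled over the `T` days, followed by a sigmoid
read-out of the final hidden state. The initial state is `h_0 = C_0 = 0`.
Loss is class-weighted binary cross-entropy

```
L = −γ·ln ỹ        if Y = 1
L = −ln(1 − ỹ)     if Y = 0
```

averaged over the batch, with γ the negative:positive count ratio of the
**full training cohort** (not of the individual bootstrap subsets — the
ratio is a property of the population being modelled, and per-subset
ratios would add gratuitous variance between learners). Scores are clipped
to `[1e−7, 1 − 1e−7]` inside the loss value; gradients are taken through
the logit, so clipping never distorts them.

Ensemble diversity comes from two sources per learner `p`: a bootstrap
resample of the training patients (size `N`, drawn with replacement —
standard bagging) and a uniformly random subset of `m` of the `D`
variables (random subspace method). Member scores are combined by an
unweighted arithmetic mean.

## Training

Gradients are exact backpropagation-through-time, implemented directly in
numpy and checked against central finite differences (relative error
≤ 1e−4 in the test suite, typically ~1e−7). The optimiser is Adam with
canonical moments (β₁ = 0.9, β₂ = 0.999, ε = 1e−8); full-batch updates by
default, with an optional seeded mini-batch mode. Weights are initialised
Glorot-uniform (`±sqrt(6/(fan_in+fan_out))`), biases at zero.

Input dropout (default rate 0.5) zeroes input features independently **at
every time step** during training, with inverted scaling so inference uses
the raw inputs. Resampling the mask per step (rather than per sequence) is
the stronger and more common regulariser for recurrent inputs; per-sequence
masking would be the other defensible reading.

Two training modes exist deliberately:

* **ensemble member** (`early_stop=False`): exactly `max_epochs` (default
  100) epochs, no hold-out. Member bias is controlled by the fixed epoch
  budget; the ensemble average controls variance.
* **standalone baseline** (`early_stop=True`): a label-stratified 10%
  validation split (stratified so both classes are always present),
  parameters returned from the epoch with the lowest validation loss.

Every learner derives its randomness from `SeedSequence((master_seed, p))`,
so learners are mutually independent, independent of training order (safe
to parallelise), and unchanged when `P` grows. A bootstrap draw that
contains a single class is redrawn (up to 100 attempts) because the
weighted loss is undefined without positives. Evaluating a `P′ < P` prefix
of a trained ensemble is therefore identical to training with `P′`, which
is how the ensemble-size sweep shares one training run.

## Preprocessing

Missing entries are filled per variable by linear interpolation in time;
leading/trailing gaps copy the nearest observed value (a line needs two
anchors), and a variable with no observation at all for a patient takes
the training-set variable mean (≈ 0 after z-scoring — the least-informative
neutral value). Imputation runs **first**, then per-variable normalization
statistics (mean, sample standard deviation with the n−1 denominator,
pooled over all patients and days of the training fold) are fitted and
applied; standard deviations are floored at 1e−8 so constant variables
normalize to 0. Statistics are always fitted on the training fold only and
serialized with the model. When a fitted model scores new patients, tracks
with no observations take the stored training mean.

Days are 1-based (`D1…DT`) in the external CSV schema, 0-based in arrays.

## Dynamic prediction

To score a patient with data through day `k`, days `k+1…T` are filled with
the day-`k` value of each variable (last observation carried forward,
applied to the imputed series — padding the imputed rather than raw values
keeps the operation deterministic and well-defined for variables missing
on day `k`) and the full-sequence model is applied. The day-`T` score
equals the static score by construction. No per-day retraining occurs.

## Metrics

AUROC is computed as the Mann–Whitney rank statistic (ties counted half);
the unit tests check it against exhaustive pair enumeration.
AUPRC uses the step-wise average-precision rule (trapezoidal interpolation
of precision-recall curves is optimistically biased). Thresholded metrics
(sensitivity, specificity, accuracy, precision, F1) count a prediction
positive iff score ≥ threshold, default 0.5; when nothing is predicted
positive, precision and F1 are reported as 0 with a flag. The decision
threshold is the single largest lever on the thresholded metrics under
class imbalance and is exposed everywhere.

The experiment harness repeats a label-stratified train/test split
(defaults: 50 repeats, 10% test), refits preprocessing per split, trains
the ensemble and optionally the baseline, and emits one tidy row per
(repeat, model, P, m, day). Stratification guarantees positives in every
test fold, which simple random 10% splits would not at desk scale.

## Synthetic cohorts

Real cohorts of this shape are access-restricted clinical data, so the
package ships a generator that reproduces the structural features the
method exploits, not clinical physiology:

* labels i.i.d. Bernoulli with positive probability `1/(1+γ)`
  (default γ = 7.5, matching a ~7.5:1 survivor:death imbalance);
* each variable track a stationary AR(1) process
  (`x_t = φ·x_{t−1} + ε_t`, default φ = 0.5, innovation sd 1) — temporal
  dependence is what the LSTM consumes;
* for positive-class patients, the first `n_informative` variables
  (default D/2) drift upward by `effect_size` (default 0.5) per day from
  `signal_onset_day` onward — concentrating signal in a known variable
  subset is what makes the random-subspace mechanism testable, and a late
  onset day creates the gradient that dynamic prediction must detect;
* entries masked missing completely at random (default rate 0.1), with
  one measurement forced back per patient so imputation always has an
  anchor.

What the generator does **not** emulate: inter-variable correlation,
reference ranges, informative (disease-driven) missingness,
variable-length stays. Results on it demonstrate algorithmic correctness
and qualitative behaviour, not clinical performance.

## Desk-scale benchmark

The standard test-suite benchmark is 600 patients, D = 12 (6 informative),
T = 10, γ = 7.5, with a 20-learner ensemble of 16-unit LSTMs (m = 6,
dropout 0.25, 60 epochs) over 10 repeated stratified 90/10 splits — sized
so the full suite runs in minutes on one CPU. With the default effect
size the 10-day accumulated signal makes the static task fully separable
(both the ensemble and the single LSTM reach AUROC ≈ 1.0, so the
ensemble-vs-single comparison holds with near-ties); that effect size is
chosen by the *harder* requirement that the late-onset variant
(signal from day 8 only, i.e. three drifted days) still reaches day-10
AUROC > 0.8 while sitting at chance through day 7. A smaller effect would
leave the dynamic study underpowered; decoupling the two would require
per-study effect sizes, which we deliberately avoid — one generator, one
default.

## Known limitations

* The ensemble-size benefit is muted on the default (near-saturated)
  benchmark; it is visible in the late-onset study and in the per-repeat
  variance of small-P ensembles.
* Full-batch Adam on long sequences is memory-proportional to `n·T·H`;
  the mini-batch mode exists but is not the default.
* The decision threshold 0.5 is a convention, not a calibration; under
  heavy imbalance the thresholded metrics are threshold-dominated.
* Multi-layer/bidirectional stacks, learner weighting, stacking and
  boosting are out of scope by design.
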