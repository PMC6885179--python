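# elstm

Ensemble-of-LSTM classification for mortality-style binary outcomes from
multivariate daily clinical time series.

## The problem

In intensive care, a patient's risk of death is encoded in the *temporal
trends* of routinely collected measurements — dozens of labs and vital signs
sampled day by day. Single recurrent classifiers capture those trends but
struggle with the heterogeneity of critical-care populations, and the
outcome of interest (death within a follow-up window) is heavily
outnumbered by survivors. This package implements an ensemble remedy
(eLSTM): many small LSTM classifiers, each trained on a *bootstrap resample*
of the patients (bagging) restricted to a *random subset of the variables*
(random subspace method), with the final risk score taken as the plain
average of the member scores.

## The model

Each patient is a matrix `V = [X_1, …, X_T]` of `D` variables over `T`
days with binary outcome `Y` (1 = death). A base classifier is a single
LSTM block unrolled over the days,

```
f_t = σ(w_f·[h_{t−1}, X_t] + b_f)        (forget gate)
i_t = σ(w_i·[h_{t−1}, X_t] + b_i)        (input gate)
o_t = σ(w_o·[h_{t−1}, X_t] + b_o)        (output gate)
C_t = f_t ∗ C_{t−1} + i_t ∗ tanh(w_c·[h_{t−1}, X_t] + b_c)
h_t = o_t ∗ tanh(C_t)
```

with a sigmoid read-out `ỹ = σ(w_ho·h_T + b_ho)` and a class-weighted
cross-entropy loss: positives weighted by γ = N_neg/N_pos, negatives by 1.
Training is Adam on exact backpropagation-through-time gradients
(implemented in numpy; the gradient is verified against finite differences
in the test suite).

The ensemble trains `P` such classifiers, learner `p` on bootstrap sample
`Subset_p` restricted to `m` of the `D` variables, and predicts

```
Ỹ = (1/P) Σ_p ỹ_p .
```

For **dynamic prediction** a patient observed only through day `k` is
padded to length `T` by carrying the day-`k` values forward (LOCF) and
scored with the same full-sequence model — one risk estimate per day, no
retraining.

Preprocessing is linear-interpolation imputation in time followed by
per-variable z-scoring with statistics pooled over the training set.
Reference defaults follow the full-scale recipe: `P=200`, `m=D/2`, 64
hidden units, input dropout 0.5, Adam at 0.01 for a fixed 100 epochs per
member (the standalone LSTM baseline instead early-stops on a 10%
validation split).

## Worked example

```python
import numpy as np
from elstm import ELSTM, EnsembleConfig, TrainSettings
from elstm.synthetic import benchmark_config, generate_cohort
from elstm.evaluate import stratified_split

cohort = generate_cohort(benchmark_config(seed=0))   # 600 patients, D=12, T=10
rng = np.random.default_rng(0)
train_idx, test_idx = stratified_split(cohort.labels, 0.1, rng)

config = EnsembleConfig(
    n_learners=20, subset_size=6,
    train_settings=TrainSettings(hidden_units=16, dropout_rate=0.25,
                                 max_epochs=60, early_stop=False),
    master_seed=0)
results = ELSTM(cohort.subset(train_idx), config).fit()
print(results.summary(test=cohort.subset(test_idx)))
```

prints

```
eLSTM ensemble results
==============================================
base learners (P)                           20
variables per learner (m)                    6
total variables (D)                         12
hidden units (H)                            16
epochs per learner                          60
dropout rate                              0.25
learning rate                             0.01
class ratio γ (neg/pos)                  9.000
training patients                          540
----------------------------------------------
test metrics (threshold = 0.5)
AUROC                                   1.0000
AUPRC                                   1.0000
sensitivity/recall                      1.0000
specificity                             1.0000
accuracy                                1.0000
precision                               1.0000
F1                                      1.0000
==============================================
```

γ = 9.0 is the survivor:death ratio of this training fold (the seed-0
cohort drew 60 deaths among 600 patients against the expected ~71) and is the
weight given to each death in the loss. The synthetic benchmark's default
class signal accumulates from day 1, which makes the 10-day task fully
separable (AUROC 1.0); the late-onset variant used in the dynamic-
prediction study (signal starting day 8) is the harder stress test — daily
AUROC stays near 0.5 through day 7 and exceeds 0.9 by day 10.

The same pipeline is available from the shell:

```bash
elstm synth --config config.yaml --out cohort.csv --labels labels.csv
elstm train --data cohort.csv --labels labels.csv --config config.yaml --out model/
elstm predict --model model/ --data cohort.csv --out scores.csv
elstm predict-daily --model model/ --data cohort.csv --out daily.csv
elstm evaluate --data cohort.csv --labels labels.csv --config config.yaml --out results.csv
```

Input is a tidy long-format CSV (`patient_id, day, variable, value`, one
row per observed measurement) plus a `patient_id, label` file.

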