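"""Discrimination metrics and the repeated-split experiment harness.

Threshold-free discrimination is measured by AUROC (the Mann–Whitney
probability that a random positive outscores a random negative, ties
counted half) and AUPRC (the step-wise average-precision rule, whose chance
level equals the positive-class prevalence — the informative curve under
heavy class imbalance).  Thresholded metrics come from the confusion matrix
at a decision cutoff (default 0.5; the choice of cutoff is the dominant
driver of sensitivity/precision trade-offs and is exposed everywhere).

:func:`run_experiment` is the repeated-random-split harness: stratified
90/10 train/test splits, preprocessing fitted on the training fold only,
the ensemble (and optionally the single-LSTM baseline) trained per split,
static and daily metrics emitted as one tidy row per (repeat, model, day).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from .cohort import Cohort, compute_class_ratio, preprocess
from .dynamic import predict_daily_scores
from .ensemble import (
    EnsembleConfig,
    EnsembleModel,
    predict_scores,
    train_ensemble,
    train_single,
)
from .nn import TrainSettings

__all__ = [
    "EvaluationReport",
    "ExperimentGrid",
    "auroc",
    "auprc",
    "thresholded_metrics",
    "evaluate_scores",
    "stratified_split",
    "run_experiment",
]


@dataclass(frozen=True)
class EvaluationReport:
    """Threshold-free and thresholded metrics for one score/label set."""

    auroc: float
    auprc: float
    sensitivity: float
    specificity: float
    accuracy: float
    precision: float
    f1: float
    threshold: float
    n_pos: int
    n_neg: int
    degenerate_precision: bool = False  # no predicted positives at threshold

    def as_dict(self) -> dict:
        return {
            "auroc": self.auroc, "auprc": self.auprc,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "precision": self.precision,
            "f1": self.f1, "threshold": self.threshold,
            "n_pos": self.n_pos, "n_neg": self.n_neg,
        }


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    return labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) statistic.

    Equals the probability that a uniformly chosen positive receives a
    higher score than a uniformly chosen negative, with ties counted half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs both classes")
    ranks = rankdata(scores)  # average ranks at ties
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (average-precision rule)."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if labels.sum() == 0:
        raise ValueError("AUPRC needs at least one positive")
    return float(average_precision_score(labels, scores))


def thresholded_metrics(scores, labels, threshold: float = 0.5) -> EvaluationReport:
    """Confusion-matrix metrics with predicted-positive iff score ≥ threshold.

    If nothing is predicted positive, precision and F1 are reported as 0
    with the ``degenerate_precision`` flag set.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        raise ValueError("thresholded metrics need both classes")
    sensitivity = tp / n_pos
    specificity = tn / n_neg
    accuracy = (tp + tn) / (n_pos + n_neg)
    degenerate = (tp + fp) == 0
    precision = 0.0 if degenerate else tp / (tp + fp)
    f1 = (0.0 if precision + sensitivity == 0
          else 2 * precision * sensitivity / (precision + sensitivity))
    return EvaluationReport(
        auroc=auroc(scores, labels), auprc=auprc(scores, labels),
        sensitivity=sensitivity, specificity=specificity, accuracy=accuracy,
        precision=precision, f1=f1, threshold=threshold,
        n_pos=n_pos, n_neg=n_neg, degenerate_precision=degenerate,
    )


def evaluate_scores(scores, labels, threshold: float = 0.5) -> EvaluationReport:
    """Full report (AUROC/AUPRC + thresholded metrics) for one score set."""
    return thresholded_metrics(scores, labels, threshold)


@dataclass(frozen=True)
class ExperimentGrid:
    """Repeated-split experiment settings.

    Reference design: 50 repeats of a stratified 90/10 split.  ``p_grid``
    evaluates sub-ensembles of the first p learners (learner seeds are
    independent of P, so a prefix equals an ensemble trained with that P);
    ``m_grid`` retrains the ensemble per subset size.
    """

    n_repeats: int = 50
    test_fraction: float = 0.1
    p_grid: tuple[int, ...] = ()
    m_grid: tuple[int, ...] = ()
    seed: int = 0
    threshold: float = 0.5
    include_baseline: bool = True
    include_daily: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


def stratified_split(labels: np.ndarray, test_fraction: float,
                     rng: np.random.Generator):
    """Label-stratified disjoint (train, test) index arrays covering all."""
    labels = np.asarray(labels)
    test_idx = []
    for cls in np.unique(labels):
        cls_idx = rng.permutation(np.flatnonzero(labels == cls))
        n_test = max(1, int(round(test_fraction * cls_idx.size)))
        if n_test >= cls_idx.size:
            n_test = cls_idx.size - 1
        test_idx.append(cls_idx[:n_test])
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(labels.size), test)
    return train, test


def _metric_row(report: EvaluationReport, **keys) -> dict:
    row = dict(keys)
    row.update(report.as_dict())
    return row


def _evaluate_model(fitted: EnsembleModel, X_test, y_test, *, rows: list,
                    threshold: float, include_daily: bool, **keys) -> None:
    T = X_test.shape[1]
    static = evaluate_scores(predict_scores(fitted, X_test), y_test, threshold)
    rows.append(_metric_row(static, phase="static", day=T, **keys))
    if include_daily:
        daily = predict_daily_scores(fitted, X_test)  # (n, T)
        for k in range(1, T + 1):
            rep = evaluate_scores(daily[:, k - 1], y_test, threshold)
            rows.append(_metric_row(rep, phase="daily", day=k, **keys))


def run_experiment(cohort: Cohort, grid: ExperimentGrid,
                   config: EnsembleConfig) -> pd.DataFrame:
    """Repeated stratified-split evaluation of the ensemble (and baseline).

    For every repeat: split, impute and normalize with training-fold
    statistics only, train the ensemble for max(p_grid ∪ {P}) learners and
    evaluate each requested sub-ensemble size, retrain per ``m_grid`` entry,
    optionally train the single-LSTM baseline; emit static metrics and the
    per-day dynamic curves.  One tidy row per (repeat, model, P, m, day);
    fully reproducible from ``grid.seed`` and ``config.master_seed``.
    """
    labels = cohort.labels
    D = cohort.n_variables
    base_m = config.resolve_subset_size(D)
    p_values = sorted(set(grid.p_grid) | {config.n_learners})
    max_p = max(p_values)
    rows: list[dict] = []
    for repeat in range(grid.n_repeats):
        split_seed = np.random.SeedSequence((grid.seed, repeat))
        rng = np.random.default_rng(split_seed)
        train_idx, test_idx = stratified_split(labels, grid.test_fraction, rng)
        (train, test), stats = preprocess(
            cohort.subset(train_idx), cohort.subset(test_idx)
        )
        X_test = test.to_array()
        y_test = test.labels
        repeat_master = int(rng.integers(2**31))

        big = train_ensemble(
            train,
            replace(config, n_learners=max_p, master_seed=repeat_master),
            stats=stats,
        )
        for p in p_values:
            _evaluate_model(
                big.truncated(p), X_test, y_test, rows=rows,
                threshold=grid.threshold,
                include_daily=grid.include_daily and p == config.n_learners,
                repeat=repeat, model="elstm", n_learners=p, subset_size=base_m,
                seed=repeat_master,
            )
        for m in grid.m_grid:
            if m == base_m:
                continue  # already covered by the main ensemble
            alt = train_ensemble(
                train,
                replace(config, subset_size=m, master_seed=repeat_master),
                stats=stats,
            )
            _evaluate_model(
                alt, X_test, y_test, rows=rows, threshold=grid.threshold,
                include_daily=False, repeat=repeat, model="elstm",
                n_learners=config.n_learners, subset_size=m,
                seed=repeat_master,
            )
        if grid.include_baseline:
            baseline_settings = replace(config.train_settings, early_stop=True)
            single = train_single(train, baseline_settings, stats=stats,
                                  seed=repeat_master)
            _evaluate_model(
                single, X_test, y_test, rows=rows, threshold=grid.threshold,
                include_daily=grid.include_daily, repeat=repeat, model="lstm",
                n_learners=1, subset_size=D, seed=repeat_master,
            )
    return pd.DataFrame(rows)
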