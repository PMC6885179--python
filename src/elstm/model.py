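"""Model/Results interface over the ensemble pipeline.

:class:`ELSTM` is constructed from a raw :class:`~elstm.cohort.Cohort`
(missing values allowed) and an :class:`~elstm.ensemble.EnsembleConfig`;
``fit()`` imputes, fits normalization statistics on the training cohort,
trains the P base learners and returns an :class:`ELSTMResults` carrying
the trained ensemble.  :class:`SingleLSTM` is the standalone one-classifier
baseline with validation-based best-epoch selection.

New data passed to the results object are imputed with the fitted
statistics (a track with no observations at all becomes the training mean,
i.e. neutral after z-scoring), so prediction never touches the training
data again and a saved model reproduces its scores bit-for-bit.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    PatientSeries,
    cohort_from_frames,
    compute_class_ratio,
    fit_normalization,
    impute_linear,
    observed_variable_means,
    read_cohort,
)
from .dynamic import predict_daily_scores
from .ensemble import (
    EnsembleConfig,
    EnsembleModel,
    load_model,
    predict_scores,
    save_model,
    train_ensemble,
    train_single,
)
from .evaluate import EvaluationReport, evaluate_scores
from .nn import TrainSettings

__all__ = ["ELSTM", "SingleLSTM", "ELSTMResults"]


class ELSTM:
    """Ensemble-of-LSTMs mortality classifier (bagging + random subspaces).

    Parameters
    ----------
    cohort:
        Training cohort; missing entries allowed (imputed during fit).
    config:
        Ensemble hyperparameters; defaults are the reference configuration
        (P=200 learners on m=D/2 variables, 100 fixed epochs each).
    """

    def __init__(self, cohort: Cohort, config: EnsembleConfig | None = None):
        self.cohort = cohort
        self.config = config if config is not None else EnsembleConfig()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, labels: pd.DataFrame,
                       config: EnsembleConfig | None = None,
                       variable_names=None, n_days=None) -> "ELSTM":
        """Build from long-format (patient_id, day, variable, value) data
        and (patient_id, label) frames."""
        return cls(cohort_from_frames(data, labels, variable_names, n_days),
                   config)

    @classmethod
    def from_csv(cls, data_path: str, labels_path: str,
                 config: EnsembleConfig | None = None, **kwargs) -> "ELSTM":
        return cls(read_cohort(data_path, labels_path, **kwargs), config)

    def fit(self) -> "ELSTMResults":
        """Impute, fit normalization on this cohort, train the P learners."""
        fill = observed_variable_means(self.cohort)
        imputed = Cohort(
            [impute_linear(p, fill) for p in self.cohort.patients],
            list(self.cohort.variable_names),
        )
        stats = fit_normalization(imputed)
        model = train_ensemble(imputed, self.config, stats=stats)
        return ELSTMResults(model, n_train=self.cohort.n_patients)


class SingleLSTM:
    """Standalone single-LSTM baseline (no bagging, early stopping on a
    stratified 10% validation split)."""

    def __init__(self, cohort: Cohort, settings: TrainSettings | None = None,
                 seed: int = 0):
        self.cohort = cohort
        self.settings = (settings if settings is not None
                         else TrainSettings(early_stop=True))
        self.seed = seed

    def fit(self) -> "ELSTMResults":
        fill = observed_variable_means(self.cohort)
        imputed = Cohort(
            [impute_linear(p, fill) for p in self.cohort.patients],
            list(self.cohort.variable_names),
        )
        stats = fit_normalization(imputed)
        model = train_single(imputed, self.settings, stats=stats,
                             seed=self.seed)
        return ELSTMResults(model, n_train=self.cohort.n_patients)


class ELSTMResults:
    """A fitted ensemble: scoring, dynamic prediction, evaluation, summary."""

    def __init__(self, model: EnsembleModel, n_train: int | None = None):
        self.model = model
        self.n_train = n_train

    # -- data preparation ---------------------------------------------------

    def _prepare(self, data: Cohort | PatientSeries) -> np.ndarray:
        """Impute new data with the fitted statistics -> (n, T, D) array."""
        patients = data.patients if isinstance(data, Cohort) else [data]
        fill = self.model.stats.mean
        return np.stack(
            [impute_linear(p, fill).values.T for p in patients]
        )

    # -- prediction ---------------------------------------------------------

    def predict(self, data: Cohort | PatientSeries) -> np.ndarray:
        """Averaged ensemble mortality score in [0, 1] per patient."""
        scores = predict_scores(self.model, self._prepare(data))
        return scores

    def predict_daily(self, data: Cohort | PatientSeries) -> np.ndarray:
        """(n, T) matrix: column k−1 scores each patient using data through
        day k, later days padded by last-value carry-forward."""
        return predict_daily_scores(self.model, self._prepare(data))

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, data: Cohort, threshold: float = 0.5) -> EvaluationReport:
        """AUROC/AUPRC plus confusion-matrix metrics on a labelled cohort."""
        return evaluate_scores(self.predict(data), data.labels, threshold)

    # -- presentation / persistence ----------------------------------------

    def summary(self, test: Cohort | None = None,
                threshold: float = 0.5) -> str:
        """Plain-text summary of the fitted ensemble (and test metrics)."""
        model = self.model
        ts = model.config.train_settings
        lines = [
            "eLSTM ensemble results",
            "=" * 46,
            f"{'base learners (P)':<28}{model.n_learners:>18}",
            f"{'variables per learner (m)':<28}"
            f"{model.learners[0].variable_indices.size:>18}",
            f"{'total variables (D)':<28}{model.stats.n_variables:>18}",
            f"{'hidden units (H)':<28}{ts.hidden_units:>18}",
            f"{'epochs per learner':<28}{ts.max_epochs:>18}",
            f"{'dropout rate':<28}{ts.dropout_rate:>18.2f}",
            f"{'learning rate':<28}{ts.learning_rate:>18.3g}",
            f"{'class ratio γ (neg/pos)':<28}{model.gamma:>18.3f}",
        ]
        if self.n_train is not None:
            lines.append(f"{'training patients':<28}{self.n_train:>18}")
        if test is not None:
            report = self.evaluate(test, threshold)
            lines += [
                "-" * 46,
                f"test metrics (threshold = {threshold:g})",
                f"{'AUROC':<28}{report.auroc:>18.4f}",
                f"{'AUPRC':<28}{report.auprc:>18.4f}",
                f"{'sensitivity/recall':<28}{report.sensitivity:>18.4f}",
                f"{'specificity':<28}{report.specificity:>18.4f}",
                f"{'accuracy':<28}{report.accuracy:>18.4f}",
                f"{'precision':<28}{report.precision:>18.4f}",
                f"{'F1':<28}{report.f1:>18.4f}",
            ]
        lines.append("=" * 46)
        return "\n".join(lines)

    def save(self, directory: str) -> None:
        save_model(self.model, directory)

    @classmethod
    def load(cls, directory: str) -> "ELSTMResults":
        return cls(load_model(directory))
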