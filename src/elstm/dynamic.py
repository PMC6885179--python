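"""Daily dynamic prediction by last-value carry-forward padding.

The ensemble is trained on fixed-length T-day sequences, but at the bedside
data arrive one day at a time.  To score a patient after day k, the days
k+1..T are padded with the day-k values (per variable, after imputation) and
the full-sequence model is applied unchanged — no per-day retraining.  The
resulting T-vector of scores tracks how the risk estimate sharpens as data
accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cohort import PatientSeries
from .ensemble import EnsembleModel, predict, predict_scores

__all__ = ["DailyScores", "pad_locf", "pad_locf_array", "predict_daily",
           "predict_daily_scores"]


@dataclass(frozen=True)
class DailyScores:
    """scores[k-1] = model output using data observed through day k."""

    scores: np.ndarray  # (T,)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1 or np.any(s < 0) or np.any(s > 1):
            raise ValueError("scores must be a vector of values in [0, 1]")
        object.__setattr__(self, "scores", s)


def pad_locf(series: PatientSeries, k: int) -> PatientSeries:
    """Carry the day-k value of every variable forward through day T.

    Days 1..k are untouched; the result is marked fully observed.  The input
    must be imputed through day k.
    """
    T = series.n_days
    if not 1 <= k <= T:
        raise ValueError(f"k must lie in [1, {T}], got {k}")
    if not series.observed[:, :k].all():
        raise ValueError("series must be imputed through day k before padding")
    values = series.values.copy()
    values[:, k:] = values[:, k - 1:k]
    return replace(series, values=values,
                   observed=np.ones_like(series.observed), observed_through=T)


def pad_locf_array(X: np.ndarray, k: int) -> np.ndarray:
    """Vectorised LOCF padding of an (n, T, D) batch at day k."""
    T = X.shape[1]
    if not 1 <= k <= T:
        raise ValueError(f"k must lie in [1, {T}], got {k}")
    out = X.copy()
    out[:, k:, :] = X[:, k - 1:k, :]
    return out


def predict_daily(model: EnsembleModel, series: PatientSeries) -> DailyScores:
    """Score one patient at every day horizon k = 1..T via LOCF padding."""
    T = series.n_days
    return DailyScores(
        scores=np.array([predict(model, pad_locf(series, k)) for k in range(1, T + 1)])
    )


def predict_daily_scores(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Daily score matrix (n, T) for an imputed (n, T, D) batch."""
    X = np.asarray(X, dtype=float)
    T = X.shape[1]
    return np.column_stack(
        [predict_scores(model, pad_locf_array(X, k)) for k in range(1, T + 1)]
    )
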