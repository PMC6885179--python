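"""Patient time-series containers and preprocessing.

A patient is a ``D × T`` matrix of clinical variables sampled once per day,
with an observed-mask for missing measurements and a binary outcome label
(1 = death within the follow-up window, 0 = survival).  A :class:`Cohort`
bundles patients sharing one variable list; its negative-to-positive class
ratio ``gamma`` is the positive-instance weight used by the training loss.

Preprocessing follows the usual two steps for daily clinical series:
per-variable linear-interpolation imputation in time, then per-variable
z-scoring with statistics pooled over all patients and days of the training
set.  Days are 1-based (``D1 .. DT``) in the external CSV schema and 0-based
in the in-memory arrays.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientSeries",
    "Cohort",
    "NormalizationStats",
    "impute_linear",
    "fit_normalization",
    "apply_normalization",
    "compute_class_ratio",
    "read_cohort",
    "cohort_from_frames",
    "write_cohort",
    "observed_variable_means",
    "preprocess",
]

#: smallest standard deviation used as a divisor; zero-variance variables
#: normalize to 0 instead of dividing by zero
STD_FLOOR = 1e-8


@dataclass(frozen=True)
class PatientSeries:
    """One patient's multivariate daily series with outcome label.

    ``values[d, t]`` is the value of variable ``d`` on day ``t`` (0-based);
    ``observed[d, t]`` marks real measurements.  ``observed_through`` is the
    last 1-based day with any recorded data.
    """

    id: str
    values: np.ndarray  # (D, T) float
    observed: np.ndarray  # (D, T) bool
    label: int
    observed_through: int = -1  # -1: derive from the mask

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        observed = np.asarray(self.observed, dtype=bool)
        if values.shape != observed.shape or values.ndim != 2:
            raise ValueError("values and observed must be matching D×T matrices")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if not np.all(np.isfinite(values[observed])):
            raise ValueError("observed entries must be finite")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "observed", observed)
        if self.observed_through == -1:
            days_with_data = np.flatnonzero(observed.any(axis=0))
            through = int(days_with_data[-1]) + 1 if days_with_data.size else 1
            object.__setattr__(self, "observed_through", through)
        if not 1 <= self.observed_through <= self.n_days:
            raise ValueError("observed_through outside [1, T]")

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_days(self) -> int:
        return self.values.shape[1]


@dataclass
class Cohort:
    """An ordered collection of patients sharing variable names and T."""

    patients: list[PatientSeries]
    variable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.patients:
            raise ValueError("cohort must contain at least one patient")
        D = self.patients[0].n_variables
        T = self.patients[0].n_days
        for p in self.patients:
            if p.n_variables != D or p.n_days != T:
                raise ValueError("all patients must share D and T")
        if not self.variable_names:
            self.variable_names = [f"var{d}" for d in range(D)]
        if len(self.variable_names) != D:
            raise ValueError("variable_names length must equal D")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_variables(self) -> int:
        return self.patients[0].n_variables

    @property
    def n_days(self) -> int:
        return self.patients[0].n_days

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.patients], dtype=int)

    @property
    def gamma(self) -> float:
        """Negative-to-positive class ratio, recomputed from membership."""
        return compute_class_ratio(self)

    def to_array(self) -> np.ndarray:
        """Stack values as an (N, T, D) tensor (time-major per patient)."""
        return np.stack([p.values.T for p in self.patients])

    def subset(self, indices: Sequence[int]) -> "Cohort":
        return Cohort([self.patients[i] for i in indices], list(self.variable_names))


@dataclass(frozen=True)
class NormalizationStats:
    """Per-variable mean/std pooled over patients and days of the training set."""

    mean: np.ndarray  # (D,)
    std: np.ndarray  # (D,)

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        std = np.asarray(self.std, dtype=float)
        if mean.shape != std.shape or mean.ndim != 1:
            raise ValueError("mean and std must be vectors of equal length")
        if np.any(std < 0):
            raise ValueError("std must be nonnegative")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "std", std)

    @property
    def n_variables(self) -> int:
        return self.mean.shape[0]


def impute_linear(
    series: PatientSeries, all_missing_fill: np.ndarray | float = 0.0
) -> PatientSeries:
    """Fill missing entries of each variable track by linear interpolation.

    Internal gaps are interpolated between the nearest observed neighbours in
    time; leading/trailing gaps are extended from the nearest observed value
    (a straight line needs two anchors).  A variable with no observation at
    all is filled with ``all_missing_fill`` (scalar or per-variable vector) —
    callers normally pass the training-set variable mean so the track becomes
    neutral (~0) after z-scoring.  Observed entries are never altered.
    """
    if not series.observed.any():
        raise ValueError(f"patient {series.id!r} has no data to impute")
    D, T = series.values.shape
    fill = np.broadcast_to(np.asarray(all_missing_fill, dtype=float), (D,))
    values = series.values.copy()
    t_grid = np.arange(T, dtype=float)
    for d in range(D):
        mask = series.observed[d]
        if mask.all():
            continue
        if not mask.any():
            values[d] = fill[d]
            continue
        # np.interp clamps outside the observed range -> constant extension
        values[d] = np.interp(t_grid, t_grid[mask], values[d, mask])
    return replace(
        series, values=values, observed=np.ones((D, T), dtype=bool), observed_through=-1
    )


def observed_variable_means(cohort: Cohort) -> np.ndarray:
    """Mean of each variable over its *observed* entries across the cohort.

    Used as the fill value for patient tracks with no observation at all.
    A variable never observed anywhere falls back to 0.
    """
    D = cohort.n_variables
    total = np.zeros(D)
    count = np.zeros(D)
    for p in cohort.patients:
        m = p.observed
        total += np.where(m, p.values, 0.0).sum(axis=1)
        count += m.sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return means


def fit_normalization(train: Cohort) -> NormalizationStats:
    """Pooled per-variable mean and sample std over all patients and days.

    The cohort must already be imputed (every entry defined).  The standard
    deviation uses the sample (n−1) denominator.
    """
    stacked = np.concatenate([p.values for p in train.patients], axis=1)  # (D, N*T)
    if not np.all(np.isfinite(stacked)):
        raise ValueError("cohort must be imputed before fitting normalization")
    mean = stacked.mean(axis=1)
    std = stacked.std(axis=1, ddof=1) if stacked.shape[1] > 1 else np.zeros_like(mean)
    return NormalizationStats(mean=mean, std=std)


def apply_normalization(series: PatientSeries, stats: NormalizationStats) -> PatientSeries:
    """z-score each variable: (x − mean) / max(std, floor)."""
    if series.n_variables != stats.n_variables:
        raise ValueError(
            f"series has {series.n_variables} variables, stats {stats.n_variables}"
        )
    denom = np.maximum(stats.std, STD_FLOOR)
    values = (series.values - stats.mean[:, None]) / denom[:, None]
    return replace(series, values=values)


def normalize_array(X: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Vectorised z-scoring of an (N, T, D) tensor."""
    if X.shape[-1] != stats.n_variables:
        raise ValueError("variable-count mismatch between data and stats")
    return (X - stats.mean) / np.maximum(stats.std, STD_FLOOR)


def compute_class_ratio(cohort: Cohort) -> float:
    """γ = N_negative / N_positive, the positive-class loss weight."""
    labels = cohort.labels
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0:
        raise ValueError("class ratio undefined: no positive instances")
    if n_neg == 0:
        raise ValueError("class ratio undefined: no negative instances")
    return n_neg / n_pos


def preprocess(
    train: Cohort, *others: Cohort
) -> tuple[list[Cohort], NormalizationStats]:
    """Impute and fit normalization on ``train``; impute ``others`` with the
    training fill values.  Returns the imputed cohorts (train first) and the
    fitted stats.  Normalization itself is applied at model boundaries so the
    stats can be serialized with the model.
    """
    fill = observed_variable_means(train)
    imputed = []
    for cohort in (train, *others):
        imputed.append(
            Cohort(
                [impute_linear(p, fill) for p in cohort.patients],
                list(cohort.variable_names),
            )
        )
    stats = fit_normalization(imputed[0])
    return imputed, stats


# ---------------------------------------------------------------------------
# tidy-CSV interface
# ---------------------------------------------------------------------------

def read_cohort(
    data_path: str,
    labels_path: str | None = None,
    variable_names: Sequence[str] | None = None,
    n_days: int | None = None,
) -> Cohort:
    """Read a cohort from the tidy long-format CSV pair.

    ``data_path`` columns: patient_id, day (1..T), variable, value (empty for
    missing).  ``labels_path`` columns: patient_id, label (0/1); omit it for
    prediction-only data (labels default to 0).  Rows absent from the data
    file are missing values.  Unknown variable names and out-of-range days
    are rejected.
    """
    data = pd.read_csv(data_path, dtype={"patient_id": str, "variable": str})
    labels = (pd.read_csv(labels_path, dtype={"patient_id": str})
              if labels_path is not None else None)
    return cohort_from_frames(data, labels, variable_names, n_days)


def cohort_from_frames(
    data: pd.DataFrame,
    labels: pd.DataFrame | None = None,
    variable_names: Sequence[str] | None = None,
    n_days: int | None = None,
) -> Cohort:
    """Build a :class:`Cohort` from long-format data/label DataFrames."""
    required = {"patient_id", "day", "variable", "value"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    if labels is not None and not {"patient_id", "label"}.issubset(labels.columns):
        raise ValueError("labels must have columns patient_id, label")

    if variable_names is None:
        variable_names = list(pd.unique(data["variable"]))
    var_index = {v: i for i, v in enumerate(variable_names)}
    unknown = set(data["variable"]) - set(var_index)
    if unknown:
        raise ValueError(f"unknown variable names in data CSV: {sorted(unknown)}")

    T = int(n_days if n_days is not None else data["day"].max())
    if (data["day"] < 1).any() or (data["day"] > T).any():
        raise ValueError(f"day indices must lie in [1, {T}]")

    label_map = (dict(zip(labels["patient_id"].astype(str),
                          labels["label"].astype(int)))
                 if labels is not None else None)
    D = len(variable_names)
    patients = []
    for pid, grp in data.groupby("patient_id", sort=False):
        pid = str(pid)
        if label_map is not None and pid not in label_map:
            raise ValueError(f"patient {pid!r} has no label")
        values = np.full((D, T), np.nan)
        observed = np.zeros((D, T), dtype=bool)
        d_idx = grp["variable"].map(var_index).to_numpy()
        t_idx = grp["day"].to_numpy(dtype=int) - 1
        vals = grp["value"].to_numpy(dtype=float)
        present = np.isfinite(vals)
        values[d_idx[present], t_idx[present]] = vals[present]
        observed[d_idx[present], t_idx[present]] = True
        patients.append(
            PatientSeries(id=pid, values=values, observed=observed,
                          label=label_map[pid] if label_map is not None else 0)
        )
    return Cohort(patients, list(variable_names))


def write_cohort(cohort: Cohort, data_path: str, labels_path: str) -> None:
    """Write the tidy long-format CSV pair (observed entries only)."""
    rows = []
    for p in cohort.patients:
        d_idx, t_idx = np.nonzero(p.observed)
        for d, t in zip(d_idx, t_idx):
            rows.append((p.id, t + 1, cohort.variable_names[d], p.values[d, t]))
    data = pd.DataFrame(rows, columns=["patient_id", "day", "variable", "value"])
    labels = pd.DataFrame(
        {"patient_id": [p.id for p in cohort.patients],
         "label": [p.label for p in cohort.patients]}
    )
    atomic_write_csv(data, data_path)
    atomic_write_csv(labels, labels_path)


def atomic_write_csv(df: pd.DataFrame, path: str) -> None:
    """Write a CSV via temp-file + rename so readers never see partial output."""
    directory = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
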