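"""Ensemble of LSTM classifiers over bootstrapped, variable-subsetted data.

Each of the P base learners trains on a bootstrap resample of the training
patients (sampled with replacement, same size N) restricted to a uniformly
random subset of m of the D variables — bagging for instance-level
diversity, the random subspace method for feature-level diversity.  At
prediction time every learner scores the instance from its own variable
subset and the ensemble output is the plain arithmetic mean of the P scores.

Per-learner randomness is derived from ``(master_seed, p)`` via a seed
sequence, so learners are independent of each other and of how many are
trained: results cannot depend on training order, and growing P never
perturbs existing learners.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .cohort import (
    Cohort,
    NormalizationStats,
    PatientSeries,
    compute_class_ratio,
    fit_normalization,
    normalize_array,
)
from .nn import LSTMParams, TrainSettings, forward_scores, train_lstm

__all__ = [
    "SubsetSpec",
    "BaseLearner",
    "EnsembleConfig",
    "EnsembleModel",
    "make_subsets",
    "train_ensemble",
    "train_single",
    "predict",
    "predict_scores",
    "save_model",
    "load_model",
]

#: format tag written into every model bundle manifest
BUNDLE_VERSION = "elstm-bundle-1"

MAX_RESAMPLE_ATTEMPTS = 100


@dataclass(frozen=True)
class SubsetSpec:
    """One learner's training subset: bootstrap rows × variable columns."""

    instance_indices: np.ndarray  # (N,) drawn with replacement
    variable_indices: np.ndarray  # (m,) distinct, sorted

    def __post_init__(self) -> None:
        var = np.asarray(self.variable_indices, dtype=int)
        if len(np.unique(var)) != var.size:
            raise ValueError("variable_indices must be distinct")
        object.__setattr__(self, "instance_indices",
                           np.asarray(self.instance_indices, dtype=int))
        object.__setattr__(self, "variable_indices", var)


@dataclass(frozen=True)
class BaseLearner:
    """A trained LSTM plus the variable subset it was trained on."""

    params: LSTMParams
    variable_indices: np.ndarray

    def __post_init__(self) -> None:
        var = np.asarray(self.variable_indices, dtype=int)
        if self.params.input_size != var.size:
            raise ValueError("params input size must match |variable_indices|")
        object.__setattr__(self, "variable_indices", var)


@dataclass(frozen=True)
class EnsembleConfig:
    """Ensemble hyperparameters.

    Reference defaults: P = 200 base classifiers, each on m = D/2 randomly
    chosen variables, trained for a fixed 100 epochs (no early stopping —
    ensemble averaging, not per-learner tuning, controls variance).
    """

    n_learners: int = 200
    subset_size: int | None = None  # None: floor(D / 2) at training time
    train_settings: TrainSettings = field(
        default_factory=lambda: TrainSettings(early_stop=False)
    )
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_learners < 1:
            raise ValueError("n_learners must be ≥ 1")
        if self.subset_size is not None and self.subset_size < 1:
            raise ValueError("subset_size must be ≥ 1")

    def resolve_subset_size(self, D: int) -> int:
        m = self.subset_size if self.subset_size is not None else max(1, D // 2)
        if m > D:
            raise ValueError(f"subset_size {m} exceeds D = {D}")
        return m


@dataclass(frozen=True)
class EnsembleModel:
    """P trained base learners plus the shared normalization statistics."""

    learners: list[BaseLearner]
    stats: NormalizationStats
    config: EnsembleConfig
    gamma: float
    variable_names: list[str]

    def __post_init__(self) -> None:
        if not self.learners:
            raise ValueError("ensemble must contain at least one learner")
        D = self.stats.n_variables
        for lr in self.learners:
            if lr.variable_indices.min() < 0 or lr.variable_indices.max() >= D:
                raise ValueError("learner variable indices out of range")

    @property
    def n_learners(self) -> int:
        return len(self.learners)

    def truncated(self, p: int) -> "EnsembleModel":
        """The sub-ensemble of the first p learners.

        Because learner seeds depend only on (master_seed, p), this equals
        the model that would have been trained with ``n_learners = p``.
        """
        return replace(self, learners=self.learners[:p],
                       config=replace(self.config, n_learners=p))


def _learner_rngs(master_seed: int, p: int):
    """Independent (subset, training) rng streams for learner p."""
    subset_ss, train_ss = np.random.SeedSequence((master_seed, p)).spawn(2)
    return np.random.default_rng(subset_ss), np.random.default_rng(train_ss)


def _draw_subset(rng: np.random.Generator, N: int, D: int, m: int) -> SubsetSpec:
    instances = rng.integers(0, N, size=N)
    variables = np.sort(rng.choice(D, size=m, replace=False))
    return SubsetSpec(instance_indices=instances, variable_indices=variables)


def make_subsets(N: int, D: int, config: EnsembleConfig) -> list[SubsetSpec]:
    """The P (bootstrap, variable-subset) specs for a cohort of N patients."""
    if N < 2:
        raise ValueError("need at least 2 instances to bootstrap")
    m = config.resolve_subset_size(D)
    return [
        _draw_subset(_learner_rngs(config.master_seed, p)[0], N, D, m)
        for p in range(config.n_learners)
    ]


def train_ensemble(train: Cohort, config: EnsembleConfig,
                   stats: NormalizationStats | None = None) -> EnsembleModel:
    """Fit the P base learners on an imputed training cohort.

    γ is computed once from the full training cohort, not per bootstrap
    subset.  A bootstrap draw that misses one class entirely is redrawn
    (the weighted loss needs both classes).  Learners share one set of
    normalization statistics, fitted here unless supplied.
    """
    y = train.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training cohort must contain both classes")
    gamma = compute_class_ratio(train)
    if stats is None:
        stats = fit_normalization(train)
    X = normalize_array(train.to_array(), stats)  # (N, T, D)
    N, _, D = X.shape
    m = config.resolve_subset_size(D)

    learners = []
    for p in range(config.n_learners):
        subset_rng, train_rng = _learner_rngs(config.master_seed, p)
        spec = _draw_subset(subset_rng, N, D, m)
        for _ in range(MAX_RESAMPLE_ATTEMPTS):
            if len(np.unique(y[spec.instance_indices])) == 2:
                break
            spec = _draw_subset(subset_rng, N, D, m)
        else:
            raise RuntimeError(
                f"learner {p}: bootstrap kept drawing a single class"
            )
        settings = replace(
            config.train_settings, seed=int(train_rng.integers(2**31))
        )
        params = train_lstm(
            X[spec.instance_indices][:, :, spec.variable_indices],
            y[spec.instance_indices],
            settings,
            gamma=gamma,
        )
        learners.append(
            BaseLearner(params=params, variable_indices=spec.variable_indices)
        )
    return EnsembleModel(learners=learners, stats=stats, config=config,
                         gamma=gamma, variable_names=list(train.variable_names))


def train_single(train: Cohort, settings: TrainSettings | None = None,
                 stats: NormalizationStats | None = None,
                 seed: int = 0) -> EnsembleModel:
    """The standalone-LSTM baseline: one classifier on all D variables,
    trained on the full (non-bootstrapped) cohort with validation-based
    best-epoch selection.  Packaged as a one-learner EnsembleModel so the
    prediction and evaluation paths are shared."""
    if settings is None:
        settings = TrainSettings(early_stop=True)
    settings = replace(settings, seed=seed)
    gamma = compute_class_ratio(train)
    if stats is None:
        stats = fit_normalization(train)
    X = normalize_array(train.to_array(), stats)
    D = X.shape[2]
    params = train_lstm(X, train.labels, settings, gamma=gamma)
    learner = BaseLearner(params=params, variable_indices=np.arange(D))
    config = EnsembleConfig(n_learners=1, subset_size=D,
                            train_settings=settings, master_seed=seed)
    return EnsembleModel(learners=[learner], stats=stats, config=config,
                         gamma=gamma, variable_names=list(train.variable_names))


def predict_scores(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Ensemble scores for an imputed (n, T, D) batch: normalize, let every
    learner score its variable subset, average the P scores."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != model.stats.n_variables:
        raise ValueError(
            f"expected {model.stats.n_variables} variables, got {X.shape[-1]}"
        )
    Xn = normalize_array(X, model.stats)
    total = np.zeros(X.shape[0])
    for learner in model.learners:
        total += forward_scores(learner.params, Xn[:, :, learner.variable_indices])
    return total / model.n_learners


def predict(model: EnsembleModel, series: PatientSeries) -> float:
    """Averaged ensemble score for a single imputed patient."""
    return float(predict_scores(model, series.values.T[None, :, :])[0])


# ---------------------------------------------------------------------------
# model bundle on disk
# ---------------------------------------------------------------------------

def _settings_dict(s: TrainSettings) -> dict:
    return asdict(s)


def save_model(model: EnsembleModel, directory: str) -> None:
    """Write a self-contained model bundle: manifest + per-learner arrays.

    The bundle holds everything prediction needs (normalization statistics,
    variable names, config, γ) and loads without the training data.
    """
    os.makedirs(directory, exist_ok=True)
    manifest = {
        "format": BUNDLE_VERSION,
        "gamma": model.gamma,
        "variable_names": model.variable_names,
        "n_learners": model.n_learners,
        "config": {
            "n_learners": model.config.n_learners,
            "subset_size": model.config.subset_size,
            "master_seed": model.config.master_seed,
            "train_settings": _settings_dict(model.config.train_settings),
        },
        "stats": {
            "mean": model.stats.mean.tolist(),
            "std": model.stats.std.tolist(),
        },
    }
    payload = json.dumps(manifest, indent=2)
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    with os.fdopen(fd, "w") as fh:
        fh.write(payload)
    os.replace(tmp, os.path.join(directory, "manifest.json"))
    for p, learner in enumerate(model.learners):
        arrays = learner.params.to_dict()
        arrays["variable_indices"] = learner.variable_indices
        np.savez(os.path.join(directory, f"learner_{p:04d}.npz"), **arrays)


def load_model(directory: str) -> EnsembleModel:
    """Load a model bundle written by :func:`save_model` (bit-exact)."""
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    if manifest.get("format") != BUNDLE_VERSION:
        raise ValueError(f"unrecognised model bundle format: {manifest.get('format')}")
    stats = NormalizationStats(
        mean=np.array(manifest["stats"]["mean"], dtype=float),
        std=np.array(manifest["stats"]["std"], dtype=float),
    )
    cfg = manifest["config"]
    config = EnsembleConfig(
        n_learners=cfg["n_learners"],
        subset_size=cfg["subset_size"],
        train_settings=TrainSettings(**cfg["train_settings"]),
        master_seed=cfg["master_seed"],
    )
    learners = []
    for p in range(manifest["n_learners"]):
        with np.load(os.path.join(directory, f"learner_{p:04d}.npz")) as data:
            arrays = {k: data[k] for k in data.files}
        var_idx = arrays.pop("variable_indices")
        learners.append(
            BaseLearner(params=LSTMParams.from_dict(arrays),
                        variable_indices=var_idx)
        )
    return EnsembleModel(learners=learners, stats=stats, config=config,
                         gamma=manifest["gamma"],
                         variable_names=list(manifest["variable_names"]))
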