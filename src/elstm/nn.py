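"""Single LSTM classifier: forward pass, analytic gradients, training.

One LSTM block (forget/input/output gates plus cell memory) is unrolled over
the T daily steps of a patient's series; a sigmoid read-out of the final
hidden state gives the mortality score.  The loss is class-weighted binary
cross-entropy: positives carry weight γ (the negative-to-positive ratio of
the training set), negatives weight 1, so the minority death class is not
drowned out by survivors.

Gradients are computed by backpropagation through time, written out by hand
in numpy, and optimised with Adam.  The contract-level functions
:func:`lstm_step`/:func:`lstm_forward` operate on single instances and exist
independently of the batched training path so they can be checked against a
scalar-loop oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "LSTMParams",
    "LSTMState",
    "TrainSettings",
    "lstm_step",
    "lstm_forward",
    "weighted_bce",
    "init_params",
    "loss_and_grads",
    "forward_scores",
    "train_lstm",
]

#: scores are clipped to [EPS, 1-EPS] inside the loss to keep log() finite
SCORE_EPS = 1e-7

WEIGHT_FIELDS = ("w_f", "w_i", "w_o", "w_c")
PARAM_FIELDS = WEIGHT_FIELDS + ("b_f", "b_i", "b_o", "b_c", "w_ho", "b_ho")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class LSTMParams:
    """Gate weights/biases and read-out weights of one LSTM classifier.

    Each gate matrix maps the concatenation ``[h_{t-1}, x_t]`` (length
    ``H + m``) to the H gate pre-activations, so its shape is ``(H, H + m)``.
    ``w_ho``/``b_ho`` are the sigmoid read-out applied to the final hidden
    state.
    """

    w_f: np.ndarray
    w_i: np.ndarray
    w_o: np.ndarray
    w_c: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray
    w_ho: np.ndarray  # (H,)
    b_ho: float

    def __post_init__(self) -> None:
        H, width = self.w_f.shape
        for name in WEIGHT_FIELDS:
            if getattr(self, name).shape != (H, width):
                raise ValueError(f"{name} shape inconsistent with w_f")
        for name in ("b_f", "b_i", "b_o", "b_c", "w_ho"):
            if getattr(self, name).shape != (H,):
                raise ValueError(f"{name} must be a length-H vector")
        if width <= H:
            raise ValueError("gate width must exceed H (needs room for inputs)")
        for f in dc_fields(self):
            if not np.all(np.isfinite(getattr(self, f.name))):
                raise ValueError(f"non-finite values in {f.name}")

    @property
    def hidden_size(self) -> int:
        return self.w_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.w_f.shape[1] - self.w_f.shape[0]

    def to_dict(self) -> dict[str, np.ndarray]:
        return {f: np.asarray(getattr(self, f), dtype=float) for f in PARAM_FIELDS}

    @classmethod
    def from_dict(cls, arrays: dict[str, np.ndarray]) -> "LSTMParams":
        kwargs = {f: np.asarray(arrays[f], dtype=float) for f in PARAM_FIELDS}
        kwargs["b_ho"] = float(kwargs["b_ho"])
        return cls(**kwargs)


class LSTMState(NamedTuple):
    """Hidden state and cell memory carried between time steps."""

    h: np.ndarray
    C: np.ndarray


@dataclass(frozen=True)
class TrainSettings:
    """Hyperparameters of one base classifier's training run.

    Defaults follow the reference recipe: 64 hidden units, input dropout 0.5,
    Adam with learning rate 0.01 for at most 100 epochs.  ``early_stop``
    selects the standalone-classifier mode (10% validation split, return the
    best-validation-loss epoch); ensemble members run exactly ``max_epochs``
    with no hold-out, trading per-learner tuning for ensemble bias control.
    """

    hidden_units: int = 64
    dropout_rate: float = 0.5
    learning_rate: float = 0.01
    max_epochs: int = 100
    validation_fraction: float = 0.1
    early_stop: bool = True
    batch_size: int | None = None  # None: full batch
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.early_stop and not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1) when early_stop")
        if self.hidden_units < 1 or self.max_epochs < 1:
            raise ValueError("hidden_units and max_epochs must be positive")


def lstm_step(params: LSTMParams, x_t: np.ndarray, prev: LSTMState) -> LSTMState:
    """One recurrence step: gates, cell update, new hidden state.

    f = σ(w_f·[h,x]+b_f); i, o analogous; C' = f∗C + i∗tanh(w_c·[h,x]+b_c);
    h' = o∗tanh(C').
    """
    x_t = np.asarray(x_t, dtype=float)
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(prev.h))
            and np.all(np.isfinite(prev.C))):
        raise ValueError("non-finite input to lstm_step")
    z = np.concatenate([prev.h, x_t])
    f = _sigmoid(params.w_f @ z + params.b_f)
    i = _sigmoid(params.w_i @ z + params.b_i)
    o = _sigmoid(params.w_o @ z + params.b_o)
    g = np.tanh(params.w_c @ z + params.b_c)
    C = f * prev.C + i * g
    h = o * np.tanh(C)
    return LSTMState(h=h, C=C)


def lstm_forward(params: LSTMParams, V: np.ndarray) -> float:
    """Score one instance: unroll from a zero state over the columns of the
    ``m × T`` matrix ``V`` and apply the sigmoid read-out to ``h_T``."""
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[0] != params.input_size:
        raise ValueError(f"V must be {params.input_size}×T")
    if V.shape[1] == 0:
        raise ValueError("empty sequence (T = 0)")
    H = params.hidden_size
    state = LSTMState(h=np.zeros(H), C=np.zeros(H))
    for t in range(V.shape[1]):
        state = lstm_step(params, V[:, t], state)
    return float(_sigmoid(params.w_ho @ state.h + params.b_ho))


def weighted_bce(score, label, gamma: float):
    """γ-weighted binary cross-entropy; mean over instances for arrays.

    −γ·ln(score) for positives, −ln(1−score) for negatives.  Scores are
    clipped away from {0, 1} to keep the logarithm finite.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    score = np.clip(np.asarray(score, dtype=float), SCORE_EPS, 1.0 - SCORE_EPS)
    label = np.asarray(label)
    loss = np.where(label == 1, -gamma * np.log(score), -np.log(1.0 - score))
    return float(np.mean(loss))


def init_params(H: int, m: int, seed: int) -> LSTMParams:
    """Glorot-uniform weights (±sqrt(6/(fan_in+fan_out))), zero biases."""
    if H < 1 or m < 1:
        raise ValueError("H and m must be ≥ 1")
    rng = np.random.default_rng(seed)
    gate_limit = np.sqrt(6.0 / ((H + m) + H))
    out_limit = np.sqrt(6.0 / (H + 1))
    weights = {f: rng.uniform(-gate_limit, gate_limit, size=(H, H + m))
               for f in WEIGHT_FIELDS}
    return LSTMParams(
        **weights,
        b_f=np.zeros(H), b_i=np.zeros(H), b_o=np.zeros(H), b_c=np.zeros(H),
        w_ho=rng.uniform(-out_limit, out_limit, size=H),
        b_ho=0.0,
    )


# ---------------------------------------------------------------------------
# batched forward / backward (training path)
# ---------------------------------------------------------------------------

def _forward_batch(params: LSTMParams, X: np.ndarray):
    """Unroll the LSTM over a batch; X has shape (n, T, m).

    Returns the pre-sigmoid logits (n,) and the per-step caches needed by
    the backward pass.
    """
    n, T, m = X.shape
    H = params.hidden_size
    h = np.zeros((n, H))
    C = np.zeros((n, H))
    cache = []
    for t in range(T):
        z = np.concatenate([h, X[:, t, :]], axis=1)  # (n, H+m)
        f = _sigmoid(z @ params.w_f.T + params.b_f)
        i = _sigmoid(z @ params.w_i.T + params.b_i)
        o = _sigmoid(z @ params.w_o.T + params.b_o)
        g = np.tanh(z @ params.w_c.T + params.b_c)
        C_new = f * C + i * g
        tanhC = np.tanh(C_new)
        h = o * tanhC
        cache.append((z, f, i, o, g, C, tanhC))
        C = C_new
    logits = h @ params.w_ho + params.b_ho
    return logits, h, cache


def forward_scores(params: LSTMParams, X: np.ndarray) -> np.ndarray:
    """Inference scores for a batch (n, T, m) — dropout inactive."""
    logits, _, _ = _forward_batch(params, np.asarray(X, dtype=float))
    return _sigmoid(logits)


def loss_and_grads(
    params: LSTMParams, X: np.ndarray, y: np.ndarray, gamma: float
) -> tuple[float, dict[str, np.ndarray]]:
    """Batch loss and its gradient w.r.t. every parameter (BPTT).

    The loss is the mean γ-weighted cross-entropy over the batch.  Gradients
    are taken through the logit (σ and log fused), so they stay exact even
    where the loss value itself is score-clipped.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, T, m = X.shape
    H = params.hidden_size
    logits, h_T, cache = _forward_batch(params, X)
    scores = _sigmoid(logits)
    loss = weighted_bce(scores, y, gamma)

    # d loss / d logit: (σ(a) − 1)·γ for positives, σ(a) for negatives
    dlogit = np.where(y == 1, gamma * (scores - 1.0), scores) / n  # (n,)

    grads = {name: np.zeros_like(np.asarray(getattr(params, name), dtype=float))
             for name in PARAM_FIELDS}
    grads["w_ho"] = h_T.T @ dlogit
    grads["b_ho"] = np.array(dlogit.sum())

    dh = np.outer(dlogit, params.w_ho)  # (n, H)
    dC = np.zeros((n, H))
    for t in range(T - 1, -1, -1):
        z, f, i, o, g, C_prev, tanhC = cache[t]
        do = dh * tanhC
        dC = dC + dh * o * (1.0 - tanhC**2)
        df = dC * C_prev
        di = dC * g
        dg = dC * i
        da_f = df * f * (1.0 - f)
        da_i = di * i * (1.0 - i)
        da_o = do * o * (1.0 - o)
        da_g = dg * (1.0 - g**2)
        grads["w_f"] += da_f.T @ z
        grads["w_i"] += da_i.T @ z
        grads["w_o"] += da_o.T @ z
        grads["w_c"] += da_g.T @ z
        grads["b_f"] += da_f.sum(axis=0)
        grads["b_i"] += da_i.sum(axis=0)
        grads["b_o"] += da_o.sum(axis=0)
        grads["b_c"] += da_g.sum(axis=0)
        dz = da_f @ params.w_f + da_i @ params.w_i \
            + da_o @ params.w_o + da_g @ params.w_c
        dh = dz[:, :H]
        dC = dC * f
    return loss, grads


class _Adam:
    """Adam optimiser over the named parameter arrays."""

    def __init__(self, params: LSTMParams, settings: TrainSettings):
        self.lr = settings.learning_rate
        self.b1, self.b2, self.eps = (
            settings.adam_beta1, settings.adam_beta2, settings.adam_eps,
        )
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.to_dict().items()}
        self.v = {k: np.zeros_like(v) for k, v in params.to_dict().items()}

    def step(self, params: LSTMParams, grads: dict[str, np.ndarray]) -> LSTMParams:
        self.t += 1
        arrays = params.to_dict()
        for k in PARAM_FIELDS:
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            arrays[k] = arrays[k] - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
        return LSTMParams.from_dict(arrays)


def _stratified_holdout(y: np.ndarray, fraction: float, rng: np.random.Generator):
    """Indices of a label-stratified (train, validation) partition."""
    val_idx = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(y == cls)
        n_val = max(1, int(round(fraction * cls_idx.size)))
        if n_val >= cls_idx.size:
            n_val = cls_idx.size - 1
        if n_val > 0:
            val_idx.append(rng.permutation(cls_idx)[:n_val])
    val = np.concatenate(val_idx) if val_idx else np.array([], dtype=int)
    train = np.setdiff1d(np.arange(y.size), val)
    return train, np.sort(val)


def train_lstm(
    X: np.ndarray,
    y: np.ndarray,
    settings: TrainSettings,
    gamma: float | None = None,
    return_history: bool = False,
):
    """Train one LSTM classifier on (n, T, m) sequences with binary labels.

    Input-feature dropout masks are resampled independently at every time
    step during training (inverted scaling; inference uses the full input).
    With ``early_stop`` a stratified validation split selects the
    best-validation-loss epoch; otherwise exactly ``max_epochs`` Adam epochs
    run.  Fully reproducible from ``settings.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 3 or X.shape[0] != y.size:
        raise ValueError("X must be (n, T, m) with matching labels")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if gamma is None:
        gamma = float((y == 0).sum() / (y == 1).sum())

    rng = np.random.default_rng(np.random.SeedSequence(settings.seed))
    n, T, m = X.shape
    if settings.early_stop:
        train_idx, val_idx = _stratified_holdout(
            y, settings.validation_fraction, rng
        )
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_val, y_val = X[val_idx], y[val_idx]
    else:
        X_tr, y_tr = X, y
        X_val = y_val = None

    params = init_params(
        settings.hidden_units, m, seed=int(rng.integers(2**31))
    )
    opt = _Adam(params, settings)
    keep = 1.0 - settings.dropout_rate
    history: dict[str, list] = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_params = params
    n_tr = X_tr.shape[0]
    batch = settings.batch_size or n_tr

    for _epoch in range(settings.max_epochs):
        order = rng.permutation(n_tr) if batch < n_tr else np.arange(n_tr)
        epoch_loss = 0.0
        for start in range(0, n_tr, batch):
            idx = order[start:start + batch]
            Xb = X_tr[idx]
            if settings.dropout_rate > 0.0:
                mask = rng.random(Xb.shape) < keep
                Xb = Xb * mask / keep
            loss, grads = loss_and_grads(params, Xb, y_tr[idx], gamma)
            params = opt.step(params, grads)
            epoch_loss += loss * idx.size
        history["train_loss"].append(epoch_loss / n_tr)
        if settings.early_stop:
            val_loss = weighted_bce(forward_scores(params, X_val), y_val, gamma)
            history["val_loss"].append(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_params = params

    final = best_params if settings.early_stop else params
    if return_history:
        history["best_val_loss"] = best_val if settings.early_stop else None
        return final, history
    return final
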