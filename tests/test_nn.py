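"""LSTM recurrence, loss, initialization and single-classifier training."""

import numpy as np
import pytest

from elstm.nn import (
    LSTMParams,
    LSTMState,
    TrainSettings,
    forward_scores,
    init_params,
    loss_and_grads,
    lstm_forward,
    lstm_step,
    train_lstm,
    weighted_bce,
)
from .oracles import lstm_forward_oracle, lstm_step_oracle, params_to_lists


def zero_params(H, m):
    zeros = np.zeros((H, H + m))
    return LSTMParams(w_f=zeros, w_i=zeros.copy(), w_o=zeros.copy(),
                      w_c=zeros.copy(), b_f=np.zeros(H), b_i=np.zeros(H),
                      b_o=np.zeros(H), b_c=np.zeros(H), w_ho=np.zeros(H),
                      b_ho=0.0)


class TestLstmStep:
    def test_zero_parameters_zero_input(self):
        params = zero_params(2, 2)
        state = lstm_step(params, np.zeros(2),
                          LSTMState(np.zeros(2), np.zeros(2)))
        np.testing.assert_allclose(state.C, 0.0)
        np.testing.assert_allclose(state.h, 0.0)

    def test_zero_parameters_nonzero_cell(self):
        # gates are all σ(0)=0.5, so C' = 0.5·2 = 1, h' = 0.5·tanh(1)
        params = zero_params(1, 1)
        state = lstm_step(params, np.zeros(1),
                          LSTMState(np.zeros(1), np.array([2.0])))
        np.testing.assert_allclose(state.C, [1.0])
        np.testing.assert_allclose(state.h, [0.5 * np.tanh(1.0)], atol=1e-12)
        assert state.h[0] == pytest.approx(0.38080, abs=1e-5)

    def test_scalar_case_matches_hand_oracle(self):
        params = init_params(1, 1, seed=3)
        state = lstm_step(params, np.array([0.7]),
                          LSTMState(np.array([0.2]), np.array([-0.4])))
        h, C = lstm_step_oracle(params_to_lists(params), [0.7], [0.2], [-0.4])
        assert state.h[0] == pytest.approx(h[0], abs=1e-10)
        assert state.C[0] == pytest.approx(C[0], abs=1e-10)

    def test_rejects_nonfinite_input(self):
        params = zero_params(1, 1)
        with pytest.raises(ValueError):
            lstm_step(params, np.array([np.nan]),
                      LSTMState(np.zeros(1), np.zeros(1)))

    def test_hidden_state_bounded_by_one(self):
        rng = np.random.default_rng(0)
        params = init_params(3, 2, seed=9)
        state = LSTMState(np.zeros(3), np.zeros(3))
        for _ in range(50):
            state = lstm_step(params, rng.normal(scale=10, size=2), state)
            assert np.all(np.abs(state.h) < 1.0)


class TestLstmForward:
    def test_zero_parameters_give_half(self):
        params = zero_params(2, 3)
        assert lstm_forward(params, np.ones((3, 4))) == pytest.approx(0.5)

    def test_saturated_readout_bias(self):
        params = zero_params(1, 1)
        params = LSTMParams.from_dict({**params.to_dict(),
                                       "b_ho": np.array(50.0)})
        assert lstm_forward(params, np.zeros((1, 3))) == pytest.approx(1.0, abs=1e-20)

    def test_chained_scalar_oracle(self):
        params = init_params(1, 1, seed=3)
        V = np.array([[0.5, -1.0, 2.0]])
        expected = lstm_forward_oracle(params_to_lists(params),
                                       [[0.5, -1.0, 2.0]])
        assert lstm_forward(params, V) == pytest.approx(expected, abs=1e-10)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            lstm_forward(zero_params(1, 1), np.zeros((1, 0)))

    def test_batched_path_agrees_with_contract_path(self):
        rng = np.random.default_rng(4)
        params = init_params(3, 2, seed=4)
        X = rng.normal(size=(6, 5, 2))
        batched = forward_scores(params, X)
        single = [lstm_forward(params, X[i].T) for i in range(6)]
        np.testing.assert_allclose(batched, single, atol=1e-12)


class TestWeightedBce:
    def test_reference_values(self):
        assert weighted_bce(0.5, 0, 3.0) == pytest.approx(np.log(2))
        assert weighted_bce(0.5, 1, 1.0) == pytest.approx(np.log(2))
        assert weighted_bce(0.5, 1, 2.0) == pytest.approx(2 * np.log(2))

    def test_gamma_one_is_standard_bce(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(0.01, 0.99, size=20)
        labels = rng.integers(0, 2, size=20)
        expected = np.mean(
            -(labels * np.log(scores) + (1 - labels) * np.log(1 - scores))
        )
        assert weighted_bce(scores, labels, 1.0) == pytest.approx(expected)

    def test_negative_loss_independent_of_gamma(self):
        assert weighted_bce(0.3, 0, 1.0) == weighted_bce(0.3, 0, 10.0)

    def test_positive_loss_increasing_in_gamma(self):
        losses = [weighted_bce(0.3, 1, g) for g in (0.5, 1.0, 2.0, 5.0)]
        assert np.all(np.diff(losses) > 0)

    def test_extreme_scores_stay_finite(self):
        assert np.isfinite(weighted_bce(0.0, 1, 5.0))
        assert np.isfinite(weighted_bce(1.0, 0, 5.0))

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError):
            weighted_bce(0.5, 1, 0.0)


class TestInitParams:
    def test_deterministic_given_seed(self):
        a, b = init_params(4, 3, seed=12), init_params(4, 3, seed=12)
        for k, v in a.to_dict().items():
            np.testing.assert_array_equal(v, b.to_dict()[k])

    def test_reference_gate_shape(self):
        # 64 hidden units with 25 input variables -> gates map R^89 -> R^64
        params = init_params(64, 25, seed=0)
        assert params.w_f.shape == (64, 89)

    def test_glorot_support_bound(self):
        params = init_params(8, 5, seed=2)
        limit = np.sqrt(6.0 / (13 + 8))
        for k in ("w_f", "w_i", "w_o", "w_c"):
            assert np.max(np.abs(params.to_dict()[k])) <= limit

    def test_biases_start_at_zero(self):
        params = init_params(3, 2, seed=5)
        for k in ("b_f", "b_i", "b_o", "b_c"):
            np.testing.assert_array_equal(params.to_dict()[k], 0.0)


def separable_data(n=120, T=6, m=4, seed=0):
    """Positive sequences drift upward; negatives are pure noise."""
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < 0.5).astype(int)
    X = rng.normal(size=(n, T, m))
    drift = 0.5 * np.arange(1, T + 1)[:, None]
    X[y == 1] += drift
    return X, y


class TestTrainLstm:
    def test_learns_separable_classes(self):
        X, y = separable_data(seed=1)
        settings = TrainSettings(hidden_units=8, dropout_rate=0.0,
                                 learning_rate=0.05, max_epochs=40,
                                 early_stop=False, seed=2)
        params = train_lstm(X, y, settings)
        scores = forward_scores(params, X)
        from .oracles import auroc_pairs_oracle
        assert auroc_pairs_oracle(scores, y) > 0.95

    def test_loss_decreases_over_training(self):
        X, y = separable_data(seed=3)
        settings = TrainSettings(hidden_units=8, dropout_rate=0.3,
                                 learning_rate=0.02, max_epochs=30,
                                 early_stop=False, seed=4)
        _, history = train_lstm(X, y, settings, return_history=True)
        assert history["train_loss"][-1] <= history["train_loss"][0]

    def test_ensemble_member_mode_runs_exactly_max_epochs(self):
        X, y = separable_data(n=30, seed=5)
        settings = TrainSettings(hidden_units=3, dropout_rate=0.0,
                                 max_epochs=100, early_stop=False, seed=6)
        _, history = train_lstm(X, y, settings, return_history=True)
        assert len(history["train_loss"]) == 100

    def test_early_stop_returns_best_validation_epoch(self):
        X, y = separable_data(seed=7)
        settings = TrainSettings(hidden_units=6, dropout_rate=0.0,
                                 learning_rate=0.05, max_epochs=25,
                                 validation_fraction=0.2, early_stop=True,
                                 seed=8)
        params, history = train_lstm(X, y, settings, return_history=True)
        assert history["best_val_loss"] == min(history["val_loss"])

    def test_same_seed_reproduces_scores(self):
        X, y = separable_data(n=40, seed=9)
        settings = TrainSettings(hidden_units=4, dropout_rate=0.5,
                                 max_epochs=10, early_stop=False, seed=10)
        holdout = np.random.default_rng(0).normal(size=(3, 6, 4))
        s1 = forward_scores(train_lstm(X, y, settings), holdout)
        s2 = forward_scores(train_lstm(X, y, settings), holdout)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_rejected(self):
        X = np.zeros((10, 3, 2))
        with pytest.raises(ValueError):
            train_lstm(X, np.zeros(10, dtype=int), TrainSettings(max_epochs=1))


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self):
        """BPTT gradients of the γ-weighted loss vs central differences."""
        rng = np.random.default_rng(0)
        params = init_params(2, 2, seed=1)
        X = rng.normal(size=(4, 3, 2))
        y = np.array([0, 1, 0, 1])
        gamma = 3.0
        _, grads = loss_and_grads(params, X, y, gamma)
        eps = 1e-6
        for name, grad in grads.items():
            arr = params.to_dict()[name]
            numeric = np.zeros_like(np.atleast_1d(np.asarray(arr, dtype=float)))
            flat_shape = numeric.shape
            for idx in np.ndindex(flat_shape):
                for sign in (+1, -1):
                    d = params.to_dict()
                    a = np.atleast_1d(np.array(d[name], dtype=float))
                    a[idx] += sign * eps
                    d[name] = a if np.asarray(arr).ndim else a[0]
                    score = forward_scores(LSTMParams.from_dict(d), X)
                    val = weighted_bce(score, y, gamma)
                    numeric[idx] += sign * val / (2 * eps)
            rel = np.abs(numeric - np.atleast_1d(grad)) / (
                np.abs(numeric) + 1e-8
            )
            assert rel.max() < 1e-4, f"gradient mismatch in {name}"
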