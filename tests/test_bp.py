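"""BP perceptron training: elementary ops, gradient correctness,
convergence and determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from bpgrn import (
    BPNetworkInferrer,
    ExpressionMatrix,
    GeneRegressor,
    InvalidInputError,
    TrainingConfig,
    backprop_step,
    forward,
    pattern_error,
    sigmoid,
    train_all_regressors,
    train_gene_regressor,
)
from bpgrn.bp import _initial_weights


def expr(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        gene_ids=[f"{prefix}{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values)


class TestElementaryOps:
    def test_sigmoid_values(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(2.0) == pytest.approx(0.8807970779778823)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(-50, 50))
    def test_sigmoid_symmetry(self, x):
        assert sigmoid(x) + sigmoid(-x) == pytest.approx(1.0)

    def test_forward(self):
        assert forward([0.0, 0.0], 0.0, [1.0, 2.0]) == 0.5
        assert forward([0.0], -1.0, [0.3]) == pytest.approx(sigmoid(1.0))
        assert forward([1.0], 0.0, [1.0]) == pytest.approx(sigmoid(1.0))

    def test_forward_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            forward([1.0, 2.0], 0.0, [1.0])

    def test_pattern_error(self):
        assert pattern_error([0.2, 0.8], [0.2, 0.8]) == 0.0
        assert pattern_error([1.0], [0.0]) == 0.5
        assert pattern_error([1.0, 0.0], [0.5, 0.5]) == 0.25
        with pytest.raises(InvalidInputError):
            pattern_error([1.0], [0.5, 0.5])


class TestBackpropStep:
    def regressor(self, weights, bias=0.0):
        n = len(weights)
        return GeneRegressor(target_gene="t",
                             input_gene_ids=[f"g{i}" for i in range(n)],
                             weights=np.asarray(weights, float), bias=bias)

    def test_exact_fit_means_no_update(self):
        reg = self.regressor([0.0, 0.0])
        out, change = backprop_step(reg, [0.3, 0.7], 0.5, TrainingConfig(),
                                    np.zeros(2))
        np.testing.assert_array_equal(out.weights, reg.weights)
        np.testing.assert_array_equal(change, 0.0)

    def test_delta_at_half_output(self):
        # o = 0.5, t = 1 => delta = o(1-o)(t-o) = 0.25 * 0.5 = 0.125
        reg = self.regressor([0.0])
        cfg = TrainingConfig(learning_rate=0.7)
        out, change = backprop_step(reg, [0.5], 1.0, cfg, np.zeros(1))
        assert change[0] == pytest.approx(0.7 * 0.125 * 0.5)

    def test_update_arithmetic_with_momentum(self):
        # hand arithmetic: w' = w + lr*delta*x + alpha*prev
        reg = self.regressor([0.2])
        cfg = TrainingConfig(learning_rate=0.7, momentum=0.5)
        x, t, prev = 0.5, 1.0, 0.04
        o = sigmoid(0.2 * 0.5)
        delta = o * (1 - o) * (t - o)
        out, change = backprop_step(reg, [x], t, cfg, np.array([prev]))
        assert change[0] == pytest.approx(0.7 * delta * x + 0.5 * prev)
        assert out.weights[0] == pytest.approx(0.2 + change[0])

    def test_trainable_bias_uses_negative_unit_input(self):
        reg = self.regressor([0.0], bias=0.0)
        cfg = TrainingConfig(bias_trainable=True)
        out, change = backprop_step(reg, [0.0], 1.0, cfg, np.zeros(2))
        # delta = 0.125; bias change = lr * delta * (-1)
        assert change[-1] == pytest.approx(-0.7 * 0.125)
        assert out.bias == pytest.approx(-0.7 * 0.125)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_update_direction_matches_finite_difference_gradient(self, seed):
        """The delta-rule change (momentum 0) equals -lr * dE/dw to 1e-5,
        with dE/dw taken by central differences of the pattern error."""
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 6)
        w = rng.uniform(-1, 1, n)
        x = rng.uniform(0, 1, n)
        b = rng.uniform(-1.5, 0.5)
        t = rng.uniform(0, 1)
        reg = GeneRegressor("t", [f"g{i}" for i in range(n)], w.copy(), b)
        cfg = TrainingConfig(learning_rate=0.7, momentum=0.5)
        _, change = backprop_step(reg, x, t, cfg, np.zeros(n))
        h = 1e-6
        for i in range(n):
            wp, wm = w.copy(), w.copy()
            wp[i] += h
            wm[i] -= h
            dE = (pattern_error([t], [forward(wp, b, x)])
                  - pattern_error([t], [forward(wm, b, x)])) / (2 * h)
            assert change[i] == pytest.approx(-0.7 * dE, abs=1e-5)


class TestTraining:
    def driver_data(self, seed=0, n_samples=60):
        """3 genes: two uniform drivers and one exact sigmoid target."""
        rng = np.random.default_rng(seed)
        x0 = rng.uniform(0, 1, n_samples)
        x1 = rng.uniform(0, 1, n_samples)
        x2 = 1.0 / (1.0 + np.exp(-(1.5 * x0 - 2.0 * x1 + 1.0)))
        return expr(np.vstack([x0, x1, x2]))

    def test_noiseless_target_converges(self):
        m = self.driver_data()
        reg = train_gene_regressor(m, "g2", TrainingConfig(seed=1))
        assert reg.converged
        assert reg.final_error < 1e-2

    def test_zero_delta_data_leaves_weights_at_init(self):
        # target constant 0.5, inputs 0, bias 0: every pattern has delta 0
        values = np.vstack([np.zeros(10), np.zeros(10), np.full(10, 0.5)])
        m = expr(values)
        cfg = TrainingConfig(bias=0.0, max_cycles=5, seed=3)
        reg = train_gene_regressor(m, "g2", cfg)
        w0 = np.delete(_initial_weights(3, cfg), 2)
        np.testing.assert_array_equal(reg.weights, w0)

    def test_single_gene_matrix_rejected(self):
        with pytest.raises(InvalidInputError):
            train_gene_regressor(expr([[0.1, 0.2]]), "g0")

    def test_whole_error_non_increasing_at_small_learning_rate(self):
        m = self.driver_data(seed=4)
        errors = []
        for cycles in range(1, 9):
            cfg = TrainingConfig(learning_rate=0.05, momentum=1e-6,
                                 max_cycles=cycles, error_tolerance=1e-12,
                                 seed=2)
            errors.append(train_gene_regressor(m, "g2", cfg).final_error)
        assert all(a >= b - 1e-12 for a, b in zip(errors, errors[1:]))

    def test_weight_matrix_structure_and_determinism(self):
        m = self.driver_data(seed=5, n_samples=20)
        cfg = TrainingConfig(max_cycles=30, seed=11)
        wm1 = train_all_regressors(m, cfg)
        wm2 = train_all_regressors(m, cfg)
        assert wm1.W.shape == (3, 3)
        np.testing.assert_array_equal(np.diag(wm1.W), 0.0)
        np.testing.assert_array_equal(wm1.W, wm2.W)  # bit-identical

    def test_two_genes_have_two_free_entries(self):
        rng = np.random.default_rng(0)
        m = expr(rng.uniform(0, 1, (2, 15)))
        wm = train_all_regressors(m, TrainingConfig(max_cycles=10))
        assert np.count_nonzero(wm.W) == 2

    def test_identical_initial_weights_across_regressors(self):
        # with a vanishing learning rate the trained weights stay at their
        # initial values: every regressor's column must reproduce the one
        # shared seed-derived draw (own entry removed)
        rng = np.random.default_rng(9)
        m = expr(rng.uniform(0, 1, (4, 8)))
        cfg = TrainingConfig(learning_rate=1e-9, momentum=1e-9, max_cycles=1,
                             seed=7)
        wm = train_all_regressors(m, cfg)
        w0 = _initial_weights(4, cfg)
        for j in range(4):
            idx = [i for i in range(4) if i != j]
            np.testing.assert_allclose(wm.W[idx, j], w0[idx], atol=1e-6)

    def test_reconstruction_is_close_for_converged_genes(self):
        m = self.driver_data(seed=6, n_samples=80)
        est = BPNetworkInferrer(random_state=1).fit(m.values.T)
        recon = est.transform(m.values.T)
        for j in range(3):
            if est.converged_[j]:
                err = 0.25 * np.sum((recon[:, j] - m.values[j]) ** 2)
                assert err < 2 * est.error_tolerance


class TestEstimator:
    def test_params_round_trip_and_clone(self):
        est = BPNetworkInferrer(learning_rate=0.3, random_state=42)
        params = est.get_params()
        assert params["learning_rate"] == 0.3
        cloned = clone(est)
        assert cloned.get_params() == params

    def test_fit_sets_sklearn_attributes(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (12, 4))  # samples x genes
        est = BPNetworkInferrer(max_cycles=10).fit(X)
        assert est.n_features_in_ == 4
        assert est.W_.shape == (4, 4)
        assert len(est.converged_) == 4

    def test_dataframe_input_names_genes(self):
        import pandas as pd
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.uniform(0, 1, (10, 3)),
                          columns=["a", "b", "c"])
        est = BPNetworkInferrer(max_cycles=5).fit(df)
        assert list(est.feature_names_in_) == ["a", "b", "c"]
        assert est.weight_matrix_.gene_ids == ["a", "b", "c"]

    def test_invalid_config_rejected(self):
        with pytest.raises(InvalidInputError):
            TrainingConfig(learning_rate=1.5)
        with pytest.raises(InvalidInputError):
            TrainingConfig(momentum=0.0)
        with pytest.raises(InvalidInputError):
            TrainingConfig(max_cycles=0)
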