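"""Forward pass, objective, gradients, Bayesian-LM training, evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biohybrid import neural_net as nn
from biohybrid.neural_net import (
    AffineScaler,
    MLPArchitecture,
    MLPModel,
    SupervisedSet,
    ann1_architecture,
    ann2_architecture,
    evaluate,
    loss,
    loss_gradient,
    make_split,
    train_bayes,
)
from oracles import loop_forward


def tiny_model(sizes, seed=0, alpha=0.3, beta=2.0):
    arch = MLPArchitecture(sizes)
    W, b = nn._init_params(arch, seed)
    p = sizes[0]
    return MLPModel(
        arch,
        W,
        b,
        AffineScaler(np.full(p, -1.0), np.full(p, 1.0)),
        AffineScaler(np.array([-1.0]), np.array([1.0])),
        alpha=alpha,
        beta=beta,
    )


def linear_dataset(n=60, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, (n, 1))
    y = 2.0 * X[:, 0] + 1.0
    tr, te, va = make_split(n, int(0.6 * n), int(0.2 * n), seed=seed)
    return SupervisedSet(X, y, tr, te, va)


class TestArchitecture:
    def test_study_network_builders(self):
        assert ann1_architecture().layer_sizes == (6, 10, 3, 1)
        assert ann2_architecture().layer_sizes == (5, 6, 2, 1)

    def test_parameter_count(self):
        assert ann1_architecture().n_params == 6 * 10 + 10 + 10 * 3 + 3 + 3 + 1
        assert ann2_architecture().n_params == 5 * 6 + 6 + 6 * 2 + 2 + 2 + 1

    def test_invalid_architectures_rejected(self):
        with pytest.raises(ValueError):
            MLPArchitecture((4, 1))
        with pytest.raises(ValueError):
            MLPArchitecture((4, 0, 1))
        with pytest.raises(ValueError):
            MLPArchitecture((4, 3, 2))


class TestScaling:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(seed=st.integers(0, 2**16))
    def test_scale_unscale_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-5, 7, (20, 3)) * rng.uniform(0.1, 10, 3)
        sc = AffineScaler.fit(X)
        assert np.allclose(sc.unscale(sc.scale(X)), X, atol=1e-12)
        scaled = sc.scale(X)
        assert scaled.min() >= -1 - 1e-12 and scaled.max() <= 1 + 1e-12

    def test_zero_range_feature_rejected(self):
        X = np.array([[1.0, 2.0], [1.0, 3.0]])
        with pytest.raises(ValueError):
            AffineScaler.fit(X)


class TestForward:
    def test_zero_network_outputs_output_range_midpoint(self):
        m = tiny_model((3, 4, 1))
        for W in m.weights:
            W[:] = 0.0
        for b in m.biases:
            b[:] = 0.0
        m.output_scale = AffineScaler(np.array([10.0]), np.array([30.0]))
        assert m.forward(np.zeros(3)) == pytest.approx(20.0)

    def test_matches_per_neuron_loop_oracle(self):
        m = tiny_model((2, 1, 1), seed=5)
        x = np.array([0.3, -0.7])
        assert m.forward_scaled(x[None, :])[0] == pytest.approx(
            loop_forward(m.weights, m.biases, x), abs=1e-12
        )
        m2 = tiny_model((4, 3, 2, 1), seed=6)
        x2 = np.array([0.1, -0.2, 0.5, 0.9])
        assert m2.forward_scaled(x2[None, :])[0] == pytest.approx(
            loop_forward(m2.weights, m2.biases, x2), abs=1e-12
        )

    def test_batched_forward_equals_sample_by_sample(self):
        m = tiny_model((3, 5, 2, 1), seed=2)
        X = np.random.default_rng(0).uniform(-1, 1, (7, 3))
        batch = m.forward(X)
        single = np.array([m.forward(x) for x in X])
        assert np.allclose(batch, single, atol=1e-14)

    def test_dimension_mismatch_rejected(self):
        m = tiny_model((3, 4, 1))
        with pytest.raises(ValueError):
            m.forward(np.zeros(5))


class TestLoss:
    def test_perfect_predictions_zero_decay_gives_zero(self):
        m = tiny_model((2, 2, 1), alpha=0.0, beta=1.0)
        X = np.random.default_rng(1).uniform(-1, 1, (9, 2))
        y = m.forward_scaled(X)
        F, E_D, E_W = loss(m, X, y)
        assert F == pytest.approx(0.0, abs=1e-24)

    def test_reduces_to_plain_sse(self):
        m = tiny_model((2, 2, 1), alpha=0.0, beta=1.0)
        X = np.random.default_rng(2).uniform(-1, 1, (9, 2))
        y = np.random.default_rng(3).uniform(-1, 1, 9)
        F, E_D, _ = loss(m, X, y)
        sse = float(np.sum((m.forward_scaled(X) - y) ** 2))
        assert F == pytest.approx(sse) and E_D == pytest.approx(sse)

    @pytest.mark.parametrize("sizes", [(6, 10, 3, 1), (5, 6, 2, 1)])
    def test_backprop_gradient_matches_finite_differences(self, sizes):
        m = tiny_model(sizes, seed=7)
        rng = np.random.default_rng(4)
        X = rng.uniform(-1, 1, (15, sizes[0]))
        y = rng.uniform(-1, 1, 15)
        g = loss_gradient(m, X, y)
        w0 = m.get_flat()
        eps = 1e-5
        fd = np.empty_like(g)
        for i in range(len(w0)):
            wp = w0.copy()
            wp[i] += eps
            m.set_flat(wp)
            Fp = loss(m, X, y)[0]
            wm = w0.copy()
            wm[i] -= eps
            m.set_flat(wm)
            Fm = loss(m, X, y)[0]
            fd[i] = (Fp - Fm) / (2 * eps)
        m.set_flat(w0)
        assert np.max(np.abs(g - fd) / np.maximum(np.abs(fd), 1e-6)) < 1e-6


class TestTraining:
    def test_linear_target_one_hidden_neuron(self):
        res = train_bayes(MLPArchitecture((1, 1, 1)), linear_dataset(), seed=0)
        ev = evaluate(res.model, linear_dataset(), "test")
        assert ev.rmse < 1e-3

    def test_same_seed_same_weights(self):
        ds = linear_dataset()
        r1 = train_bayes(MLPArchitecture((1, 3, 1)), ds, max_epochs=50, seed=4)
        r2 = train_bayes(MLPArchitecture((1, 3, 1)), ds, max_epochs=50, seed=4)
        assert np.array_equal(r1.model.get_flat(), r2.model.get_flat())

    def test_noisy_sine_effective_parameters_below_capacity(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(-1, 1, (110, 1))
        y = np.sin(3 * X[:, 0]) + rng.normal(0, 0.05, 110)
        tr, te, va = make_split(110, 70, 20, seed=5)
        ds = SupervisedSet(X, y, tr, te, va)
        res = train_bayes(MLPArchitecture((1, 6, 2, 1)), ds, seed=0)
        n_w = MLPArchitecture((1, 6, 2, 1)).n_params
        assert 0 < res.gamma < n_w

    def test_accepted_steps_never_increase_objective(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, (80, 2))
        y = X[:, 0] ** 2 - 0.5 * X[:, 1] + rng.normal(0, 0.02, 80)
        tr, te, va = make_split(80, 50, 15, seed=6)
        res = train_bayes(MLPArchitecture((2, 4, 1)), SupervisedSet(X, y, tr, te, va), seed=1)
        # within each epoch, at that epoch's (alpha, beta)
        assert all(h["F_post"] <= h["F_pre"] + 1e-12 for h in res.history)

    def test_empty_training_split_rejected(self):
        X = np.zeros((4, 1))
        y = np.zeros(4)
        ds = SupervisedSet(X, y, [], [0, 1], [2, 3])
        with pytest.raises(ValueError):
            train_bayes(MLPArchitecture((1, 2, 1)), ds)


class TestEvaluate:
    def make_constant_model(self, value, n_inputs=1):
        m = tiny_model((n_inputs, 1, 1))
        for W in m.weights:
            W[:] = 0.0
        for b in m.biases:
            b[:] = 0.0
        m.output_scale = AffineScaler(np.array([value - 1.0]), np.array([value + 1.0]))
        return m

    def test_perfect_predictions_give_zero_errors(self):
        m = self.make_constant_model(5.0)
        ds = SupervisedSet(np.zeros((3, 1)), np.full(3, 5.0), [0], [1], [2])
        ev = evaluate(m, ds, "validation")
        assert ev.rmse == pytest.approx(0.0) and ev.max_rel_err == pytest.approx(0.0)

    def test_single_point_relative_error_arithmetic(self):
        m = self.make_constant_model(9.4)
        ds = SupervisedSet(np.zeros((2, 1)), np.array([10.0, 10.0]), [0], [], [1])
        ev = evaluate(m, ds, "validation")
        assert ev.max_rel_err == pytest.approx(0.06)

    def test_floor_excludes_small_observations_from_relative_error(self):
        m = self.make_constant_model(1.0)
        y = np.array([0.0005, 2.0, 0.0])  # first and last below floor
        ds = SupervisedSet(np.zeros((3, 1)), y, [], [], [0, 1, 2])
        ev = evaluate(m, ds, "validation", rel_floor=1e-3)
        assert ev.n_rel == 1
        assert ev.max_rel_err == pytest.approx(0.5)  # only the 2.0 point counts
        # but all points enter the RMSE
        assert ev.rmse == pytest.approx(
            np.sqrt(np.mean((1.0 - y) ** 2))
        )

    def test_empty_subset_rejected(self):
        m = self.make_constant_model(1.0)
        ds = SupervisedSet(np.zeros((2, 1)), np.ones(2), [0, 1], [], [])
        with pytest.raises(ValueError):
            evaluate(m, ds, "validation")


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, tmp_path):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 3, (50, 2))
        y = X[:, 0] - X[:, 1] ** 2
        tr, te, va = make_split(50, 30, 10, seed=8)
        res = train_bayes(
            MLPArchitecture((2, 3, 1)), SupervisedSet(X, y, tr, te, va), max_epochs=40, seed=0
        )
        path = tmp_path / "model.json"
        nn.save_model(path, res.model)
        loaded = nn.load_model(path)
        assert np.allclose(loaded.forward(X), res.model.forward(X), atol=1e-12)
        assert loaded.alpha == res.model.alpha and loaded.beta == res.model.beta


class TestSplits:
    def test_split_is_disjoint_and_covering(self):
        tr, te, va = make_split(144, 70, 24, seed=0)
        assert len(tr) == 70 and len(te) == 24 and len(va) == 50
        assert len(np.union1d(np.union1d(tr, te), va)) == 144

    def test_forced_validation_rows_stay_in_validation(self):
        forced = np.arange(10, 38)
        tr, te, va = make_split(140, 70, 21, seed=3, forced_val=forced)
        assert np.all(np.isin(forced, va))
        assert not np.any(np.isin(forced, tr)) and not np.any(np.isin(forced, te))
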