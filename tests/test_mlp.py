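import dataclasses
import math

import numpy as np
import pytest
from scipy.special import expit

import mirscreen as ms
from mirscreen import mlp


def _fd_gradient(model, X, y, l2=1e-4, eps=1e-6):
    p0 = mlp._pack(model)
    out = np.empty_like(p0)
    for i in range(len(p0)):
        pp, pm = p0.copy(), p0.copy()
        pp[i] += eps
        pm[i] -= eps
        fp = mlp._loss_grad(pp, mlp._standardize(model, X), y, model.spec, l2)[0]
        fm = mlp._loss_grad(pm, mlp._standardize(model, X), y, model.spec, l2)[0]
        out[i] = (fp - fm) / (2 * eps)
    return out


class TestInit:
    def test_seed_determinism(self):
        spec = ms.MLPSpec(n_inputs=4, n_hidden=3, seed=7)
        a, b = ms.init_mlp(spec), ms.init_mlp(spec)
        assert np.array_equal(a.W1, b.W1) and a.b2 == b.b2

    def test_zero_init_sd_predicts_half(self, rng):
        model = ms.init_mlp(ms.MLPSpec(n_inputs=3, n_hidden=2, weight_init_sd=0.0))
        assert ms.forward(model, rng.normal(size=3)) == 0.5

    @pytest.mark.parametrize("p,h", [(14, 5), (7, 10), (1, 1)])
    def test_parameter_count(self, p, h):
        model = ms.init_mlp(ms.MLPSpec(n_inputs=p, n_hidden=h))
        assert model.n_parameters == p * h + h + h + 1
        assert len(mlp._pack(model)) == model.n_parameters


class TestForward:
    def test_hand_computed_single_unit(self):
        spec = ms.MLPSpec(n_inputs=1, n_hidden=1, hidden_link="linear")
        model = ms.MLPModel(
            spec=spec, W1=np.array([[1.0]]), b1=np.zeros(1),
            w2=np.array([2.0]), b2=0.0,
        )
        assert ms.forward(model, np.array([1.0])) == pytest.approx(expit(2.0))

    def test_tanh_sign_symmetry(self, rng):
        spec = ms.MLPSpec(n_inputs=3, n_hidden=4, hidden_link="tanh", seed=2)
        model = ms.init_mlp(spec)
        flipped = dataclasses.replace(
            model, W1=-model.W1, b1=-model.b1, w2=-model.w2
        )
        x = rng.normal(size=(20, 3))
        assert np.allclose(ms.forward(model, x), ms.forward(flipped, x))

    def test_length_mismatch_rejected(self):
        model = ms.init_mlp(ms.MLPSpec(n_inputs=3, n_hidden=2))
        with pytest.raises(ValueError, match="features"):
            ms.forward(model, np.zeros(4))

    def test_exponential_link_is_finite_at_extremes(self):
        model = ms.init_mlp(ms.MLPSpec(n_inputs=2, n_hidden=3,
                                       hidden_link="exponential", seed=1))
        p = ms.forward(model, np.array([1e3, -1e3]))
        assert 0.0 < p < 1.0


class TestLoss:
    def test_uninformative_model_gives_log2(self, rng):
        model = ms.init_mlp(ms.MLPSpec(n_inputs=2, n_hidden=2, weight_init_sd=0.0))
        X = rng.normal(size=(10, 2))
        y = (rng.random(10) < 0.5).astype(int)
        assert ms.loss(model, X, y, l2=0.0) == pytest.approx(math.log(2))

    def test_matches_direct_formula(self, rng):
        """Independent recomputation: explicit BCE + penalty, no shortcuts."""
        for seed in range(5):
            spec = ms.MLPSpec(n_inputs=3, n_hidden=2, hidden_link="logistic", seed=seed)
            model = ms.init_mlp(spec)
            X = rng.normal(size=(12, 3))
            y = (rng.random(12) < 0.4).astype(float)
            p = np.array([ms.forward(model, row) for row in X])
            direct = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
            direct += 1e-4 * (np.sum(model.W1**2) + np.sum(model.w2**2))
            assert ms.loss(model, X, y) == pytest.approx(direct, rel=1e-10)

    def test_confident_correct_predictions_drive_loss_to_zero(self):
        spec = ms.MLPSpec(n_inputs=1, n_hidden=1, hidden_link="linear")
        model = ms.MLPModel(spec=spec, W1=np.array([[50.0]]), b1=np.zeros(1),
                            w2=np.array([1.0]), b2=0.0)
        X = np.array([[-1.0], [1.0]])
        assert ms.loss(model, X, np.array([0, 1]), l2=0.0) < 1e-10

    def test_empty_matrix_rejected(self):
        model = ms.init_mlp(ms.MLPSpec(n_inputs=2, n_hidden=2))
        with pytest.raises(ValueError, match="empty"):
            ms.loss(model, np.empty((0, 2)), np.empty(0))


class TestGradient:
    def test_output_bias_gradient_zero_at_symmetric_start(self, rng):
        model = ms.init_mlp(ms.MLPSpec(n_inputs=2, n_hidden=2, weight_init_sd=0.0))
        X = rng.normal(size=(10, 2))
        y = np.array([0, 1] * 5)
        g = ms.gradient(model, X, y, l2=0.0)
        assert g[-1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("link", mlp.HIDDEN_LINKS)
    def test_matches_finite_differences(self, link, rng):
        for seed in range(3):
            spec = ms.MLPSpec(n_inputs=3, n_hidden=3, hidden_link=link, seed=seed)
            model = ms.init_mlp(spec)
            X = rng.normal(size=(15, 3))
            y = (rng.random(15) < 0.5).astype(float)
            g = ms.gradient(model, X, y)
            fd = _fd_gradient(model, X, y)
            assert np.linalg.norm(g - fd) / np.linalg.norm(fd) < 1e-5

    def test_penalty_gradient_is_two_lambda_weights(self, rng):
        model = ms.init_mlp(ms.MLPSpec(n_inputs=2, n_hidden=2, seed=3))
        X = rng.normal(size=(8, 2))
        y = (rng.random(8) < 0.5).astype(float)
        lam = 0.05
        delta = ms.gradient(model, X, y, l2=lam) - ms.gradient(model, X, y, l2=0.0)
        expected = np.concatenate([
            2 * lam * model.W1.ravel(), np.zeros(2), 2 * lam * model.w2, [0.0]
        ])
        assert np.allclose(delta, expected)


class TestTrain:
    def test_loss_never_worse_than_initialization(self, rng):
        model = ms.init_mlp(ms.MLPSpec(n_inputs=3, n_hidden=4, seed=0))
        X = rng.normal(size=(30, 3))
        y = (X[:, 1] > 0).astype(int)
        before = ms.loss(model, X, y)
        trained = ms.train(model, X, y, max_iter=50)
        assert trained.training["loss"] <= before

    def test_separable_1d_reaches_perfect_accuracy(self):
        X = np.concatenate([np.full(10, -1.0), np.full(10, 1.0)])[:, None]
        y = np.concatenate([np.zeros(10), np.ones(10)])
        model = ms.init_mlp(ms.MLPSpec(n_inputs=1, n_hidden=1,
                                       hidden_link="linear", seed=1))
        trained = ms.train(model, X, y, max_iter=100)
        calls = ms.forward(trained, X) >= 0.5
        assert np.array_equal(calls, y.astype(bool))

    def test_xor_solvable_with_two_tanh_units(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        X = np.tile(X, (3, 1))
        y = np.tile(np.array([0, 1, 1, 0]), 3)
        solved = False
        for seed in range(10):
            model = ms.init_mlp(ms.MLPSpec(n_inputs=2, n_hidden=2,
                                           hidden_link="tanh", seed=seed,
                                           weight_init_sd=1.0))
            trained = ms.train(model, X, y, max_iter=200, l2=0.0)
            if np.array_equal(ms.forward(trained, X) >= 0.5, y.astype(bool)):
                solved = True
                break
        assert solved

    def test_single_class_rejected(self, rng):
        model = ms.init_mlp(ms.MLPSpec(n_inputs=2, n_hidden=2))
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValueError, match="single class"):
            ms.train(model, X, np.ones(5))

    def test_training_is_bit_reproducible(self, rng):
        X = rng.normal(size=(25, 3))
        y = (X[:, 0] > 0).astype(int)
        out = []
        for _ in range(2):
            model = ms.init_mlp(ms.MLPSpec(n_inputs=3, n_hidden=3, seed=11))
            out.append(ms.train(model, X, y, max_iter=40))
        assert np.array_equal(out[0].W1, out[1].W1)
        assert out[0].training == out[1].training
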