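"""SAE-SM: gradient correctness, sparsity, training contracts."""

import numpy as np
import pytest

from subloc2l.sae import (
    SAEConfig,
    ae_grad,
    ae_loss,
    fine_tune,
    fit_sae,
    net_grad,
    net_loss,
    pretrain_stack,
    sigmoid,
    softmax,
    train_autoencoder,
)
from oracles import finite_diff_grads


def _rel_err(a, b):
    return np.abs(a - b).max() / (np.abs(b).max() + 1e-12)


class TestGradientCorrectness:
    def test_autoencoder_gradient_matches_finite_differences(self, rng):
        X = rng.random((5, 4))
        W1 = rng.normal(0, 0.5, (3, 4))
        W2 = rng.normal(0, 0.5, (4, 3))
        params = [W1, np.zeros(3) + 0.1, W2, np.zeros(4) - 0.1]
        analytic = ae_grad(tuple(params), X, 0.05, 3.0, 1e-4)
        numeric = finite_diff_grads(
            lambda p: ae_loss(p, X, 0.05, 3.0, 1e-4), params
        )
        for a, n in zip(analytic, numeric):
            assert _rel_err(a, n) < 1e-5

    def test_network_gradient_matches_finite_differences(self, rng):
        X = rng.random((6, 4))
        Y = np.eye(3)[rng.integers(0, 3, 6)]
        params = [
            rng.normal(0, 0.5, (3, 4)), rng.normal(0, 0.1, 3),
            rng.normal(0, 0.5, (2, 3)), rng.normal(0, 0.1, 2),
            rng.normal(0, 0.5, (3, 2)), rng.normal(0, 0.1, 3),
        ]
        analytic = net_grad(tuple(params), X, Y, 1e-4)
        numeric = finite_diff_grads(lambda p: net_loss(p, X, Y, 1e-4), params)
        for a, n in zip(analytic, numeric):
            assert _rel_err(a, n) < 1e-5

    def test_kl_penalty_zero_at_target(self):
        # KL(rho || rho) = 0: loss with beta high equals loss with beta 0
        # when the mean activation equals the target exactly.
        X = np.full((4, 2), 0.5)
        W1 = np.zeros((2, 2))
        rho = 0.5  # sigmoid(0) = 0.5 mean activation
        params = (W1, np.zeros(2), np.zeros((2, 2)), np.zeros(2))
        assert ae_loss(params, X, rho, 100.0, 0.0) == pytest.approx(
            ae_loss(params, X, rho, 0.0, 0.0)
        )


class TestPretraining:
    def test_reconstruction_error_decreases(self, rng):
        from subloc2l.sae import _descend, _glorot

        X = rng.random((20, 6))
        g = np.random.default_rng(0)
        params = [_glorot(g, 6, 6), np.zeros(6), _glorot(g, 6, 6), np.zeros(6)]
        before = ae_loss(tuple(params), X, 0.05, 0.0, 0.0)
        after_params = _descend(
            params, lambda p: ae_grad(tuple(p), X, 0.05, 0.0, 0.0), 200, 0.05
        )
        after = ae_loss(tuple(after_params), X, 0.05, 0.0, 0.0)
        assert after < before

    def test_sparsity_penalty_pulls_activations_toward_target(self, rng):
        X = rng.random((30, 8))
        base = dict(hidden1=6, hidden2=4, pretrain_epochs=150, seed=3)
        enc_sparse, _ = pretrain_stack(X, SAEConfig(sparsity_weight=3.0, sparsity_target=0.05, **base), 2)
        enc_plain, _ = pretrain_stack(X, SAEConfig(sparsity_weight=0.0, sparsity_target=0.05, **base), 2)
        act_sparse = sigmoid(X @ enc_sparse[0].T + enc_sparse[1]).mean()
        act_plain = sigmoid(X @ enc_plain[0].T + enc_plain[1]).mean()
        assert abs(act_sparse - 0.05) < abs(act_plain - 0.05)

    def test_same_seed_identical_weights(self, rng):
        X = rng.random((15, 5))
        cfg = SAEConfig(hidden1=4, hidden2=3, pretrain_epochs=30, seed=11)
        a = pretrain_stack(X, cfg, 2)
        b = pretrain_stack(X, cfg, 2)
        for (wa, ba), (wb, bb) in zip(a, b):
            assert np.array_equal(wa, wb) and np.array_equal(ba, bb)

    def test_second_encoder_sees_first_layer_activations(self, rng):
        X = rng.random((15, 5))
        cfg = SAEConfig(hidden1=4, hidden2=3, pretrain_epochs=30, seed=11)
        enc1, enc2 = pretrain_stack(X, cfg, 2)
        # retrain encoder 2 on externally recomputed h(1): must be identical
        H1 = sigmoid(X @ enc1[0].T + enc1[1])
        g = np.random.default_rng(cfg.seed)
        train_autoencoder(X, 5, 4, cfg, g)  # advance rng through encoder 1
        W2, b2 = train_autoencoder(H1, 4, 3, cfg, g)
        assert np.array_equal(W2, enc2[0]) and np.array_equal(b2, enc2[1])


class TestFineTuning:
    def test_separable_toy_reaches_perfect_training_accuracy(self, rng):
        # 2 classes, 2 features, 4-sigma margin; an independent logistic
        # fit verifies achievability.
        from sklearn.linear_model import LogisticRegression

        X = rng.normal(0, 1, (40, 2))
        y = np.repeat([1, 2], 20)
        X[y == 2, 0] += 8.0
        assert LogisticRegression(C=1e4).fit(X, y).score(X, y) == 1.0
        model = fit_sae(X, y, SAEConfig(hidden1=4, hidden2=3, pretrain_epochs=50, finetune_epochs=200))
        assert (model.predict(X) == y).mean() == 1.0

    def test_zero_epochs_leaves_pretrained_encoders_untouched(self, rng):
        X = rng.random((20, 5))
        y = np.repeat([1, 2], 10)
        cfg = SAEConfig(hidden1=4, hidden2=3, pretrain_epochs=20, finetune_epochs=0, seed=5)
        enc1, enc2 = pretrain_stack(X, cfg, 2)
        model = fine_tune(enc1, enc2, X, y, cfg)
        assert np.array_equal(model.W1, enc1[0])
        assert np.array_equal(model.W2, enc2[0])

    def test_loss_does_not_increase_over_training(self, rng):
        X = rng.random((30, 4))
        y = rng.integers(1, 3, 30)
        cfg = SAEConfig(hidden1=3, hidden2=3, pretrain_epochs=20, seed=2)
        enc1, enc2 = pretrain_stack(X, cfg, 2)
        classes = np.unique(y)
        Y = (y[:, None] == classes[None, :]).astype(float)
        m0 = fine_tune(enc1, enc2, X, y, SAEConfig(hidden1=3, hidden2=3, finetune_epochs=0, seed=2))
        m1 = fine_tune(enc1, enc2, X, y, SAEConfig(hidden1=3, hidden2=3, finetune_epochs=100, seed=2))

        def loss(m):
            return net_loss((m.W1, m.b1, m.W2, m.b2, m.Ws, m.bs), X, Y, 1e-4)

        assert loss(m1) <= loss(m0)

    def test_missing_class_rejected(self, rng):
        X = rng.random((10, 3))
        y = np.ones(10, dtype=int)
        cfg = SAEConfig(hidden1=2, hidden2=2, pretrain_epochs=1)
        enc1, enc2 = pretrain_stack(X, cfg, 2)
        with pytest.raises(ValueError):
            fine_tune(enc1, enc2, X, y, cfg, n_classes=2)


class TestPrediction:
    def test_rows_on_probability_simplex(self, rng):
        X = rng.normal(0, 2, (25, 4))
        y = rng.integers(1, 4, 25)
        while np.unique(y).size < 3:
            y = rng.integers(1, 4, 25)
        model = fit_sae(X, y, SAEConfig(hidden1=3, hidden2=3, pretrain_epochs=10, finetune_epochs=10))
        P = model.predict_proba(rng.normal(0, 2, (7, 4)))
        assert np.all(P >= 0)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-9)

    def test_zero_head_gives_uniform_rows(self, rng):
        X = rng.random((5, 3))
        model = fit_sae(X, np.array([1, 1, 2, 2, 1]), SAEConfig(hidden1=2, hidden2=2, pretrain_epochs=1, finetune_epochs=1))
        model.Ws = np.zeros_like(model.Ws)
        model.bs = np.zeros_like(model.bs)
        assert np.allclose(model.predict_proba(X), 0.5)

    def test_hand_computed_forward_pass(self):
        import subloc2l.sae as sae_mod

        W1 = np.array([[0.5, -0.2]])
        W2 = np.array([[1.0]])
        Ws = np.array([[2.0], [-1.0]])
        model = sae_mod.SAEModel(
            W1=W1, b1=np.array([0.1]), W2=W2, b2=np.array([-0.3]),
            Ws=Ws, bs=np.array([0.0, 0.5]),
            classes_=np.array([1, 2]),
            scale_min=np.zeros(2), scale_range=np.ones(2),
        )
        x = np.array([[0.4, 0.6]])
        h1 = 1 / (1 + np.exp(-(0.5 * 0.4 - 0.2 * 0.6 + 0.1)))
        h2 = 1 / (1 + np.exp(-(1.0 * h1 - 0.3)))
        logits = np.array([2.0 * h2, -1.0 * h2 + 0.5])
        expect = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(model.predict_proba(x)[0], expect)

    def test_dimension_mismatch_rejected(self, rng):
        X = rng.random((10, 3))
        model = fit_sae(X, np.array([1, 2] * 5), SAEConfig(hidden1=2, hidden2=2, pretrain_epochs=1, finetune_epochs=1))
        with pytest.raises(ValueError):
            model.predict_proba(rng.random((2, 4)))

    def test_serialization_round_trip(self, rng, tmp_path):
        X = rng.random((12, 3))
        y = np.array([1, 2] * 6)
        model = fit_sae(X, y, SAEConfig(hidden1=2, hidden2=2, pretrain_epochs=5, finetune_epochs=5))
        path = tmp_path / "model.json"
        model.save(path)
        from subloc2l.sae import SAEModel

        loaded = SAEModel.load(path)
        assert np.array_equal(loaded.predict_proba(X), model.predict_proba(X))
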