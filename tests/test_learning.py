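"""Tests for learning signals, broadcast modes, accumulators, and the
supervised training loop."""

import numpy as np
import pytest

from eprop import (GradientAccumulator, LearningMode, NetworkConfig,
                   accumulate_recurrent_updates, adaptive_broadcast_update,
                   classification_learning_signal, initialize_weights,
                   make_broadcast, output_layer_updates,
                   regression_learning_signal, run_trial, train_supervised)
from eprop.config import ConfigurationError
from eprop.eligibility import eligibility_history
from eprop.learning import _forward_learn_batch, evaluate
from eprop.losses import output_error, softmax
from eprop.oracle import backward_pass
from eprop.tasks import PatternRegressionParams, PatternRegressionTask

from conftest import random_spikes


class TestBroadcast:
    def test_symmetric_is_transpose(self, rng):
        w_out = rng.normal(size=(3, 7))
        b = make_broadcast("symmetric", w_out)
        np.testing.assert_array_equal(b, w_out.T)

    def test_zero_output_weights_silence_signals(self):
        b = make_broadcast("symmetric", np.zeros((2, 5)))
        L = regression_learning_signal(np.ones(2), np.zeros(2), b)
        assert (L == 0).all()

    def test_random_is_seed_deterministic(self, rng):
        w_out = rng.normal(size=(2, 6))
        b1 = make_broadcast("random", w_out, np.random.default_rng(5))
        b2 = make_broadcast("random", w_out, np.random.default_rng(5))
        np.testing.assert_array_equal(b1, b2)

    def test_unknown_mode(self):
        with pytest.raises(ConfigurationError):
            make_broadcast("mirror", np.zeros((1, 1)))


class TestLearningSignals:
    def test_regression_zero_error(self):
        b = np.ones((4, 2))
        y = np.array([0.3, -0.1])
        assert (regression_learning_signal(y, y, b) == 0).all()

    def test_regression_hand_value_and_linearity(self):
        b = np.array([[2.0]])
        L = regression_learning_signal(np.array([0.5]), np.array([0.0]), b)
        assert L[0] == pytest.approx(1.0)
        La = regression_learning_signal(np.array([1.5]), np.array([0.0]), b)
        assert La[0] == pytest.approx(3 * L[0])

    def test_classification_equal_logits(self):
        b = np.eye(2)
        y = np.array([1.3, 1.3])
        pi_star = np.array([1.0, 0.0])
        L = classification_learning_signal(y, pi_star, b)
        np.testing.assert_allclose(L, [-0.5, 0.5])

    def test_softmax_normalization(self, rng):
        y = rng.normal(size=(10, 4)) * 5
        assert softmax(y).sum(axis=1) == pytest.approx(np.ones(10))


class TestAccumulator:
    def test_zero_signal_means_no_change(self, small_config):
        acc = GradientAccumulator.zeros(small_config)
        ebar = np.ones((small_config.n_rec, small_config.n_rec))
        accumulate_recurrent_updates(acc, np.zeros(small_config.n_rec), ebar)
        assert np.abs(acc.dw_rec).max() == 0.0

    def test_single_step_product(self, small_config, rng):
        acc = GradientAccumulator.zeros(small_config)
        L = rng.normal(size=small_config.n_rec)
        ebar = rng.normal(size=(small_config.n_rec, small_config.n_rec))
        accumulate_recurrent_updates(acc, L, ebar, eta=0.1)
        expected = -0.1 * L[:, None] * ebar
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(acc.dw_rec, expected)

    def test_reset_is_idempotent(self, small_config, rng):
        acc = GradientAccumulator.zeros(small_config)
        accumulate_recurrent_updates(acc, rng.normal(size=small_config.n_rec),
                                     rng.normal(size=(small_config.n_rec,
                                                      small_config.n_rec)))
        acc.reset()
        assert np.abs(acc.dw_rec).max() == 0.0
        acc.reset()
        assert np.abs(acc.dw_rec).max() == 0.0


class TestOutputUpdates:
    def test_matches_oracle_readout_gradient(self, rng):
        cfg = NetworkConfig(n_in=3, n_rec=5, n_out=2, v_th=0.5)
        w = initialize_weights(cfg, rng, gain=1.2)
        x = random_spikes(rng, 20, 3)
        target = rng.normal(size=(20, 2))
        rec = run_trial(w, x, cfg)
        exact = backward_pass(rec, w, cfg, target, "regression")
        err = output_error(rec.y, target, rec.loss_mask, "regression")
        acc = GradientAccumulator.zeros(cfg)
        z_bar, kern = np.zeros(cfg.n_rec), 0.0
        for t in range(20):
            z_bar = cfg.kappa * z_bar + rec.z[t]
            kern = cfg.kappa * kern + 1.0
            output_layer_updates(acc, err[t], z_bar, bias_kernel=kern)
        np.testing.assert_allclose(-acc.dw_out, exact.dw_out, atol=1e-10)
        np.testing.assert_allclose(-acc.db_out, exact.db_out, atol=1e-10)

    def test_silent_network_updates_bias_only(self):
        cfg = NetworkConfig(n_in=1, n_rec=2, n_out=1)
        acc = GradientAccumulator.zeros(cfg)
        output_layer_updates(acc, np.array([0.7]), np.zeros(2), bias_kernel=1.0)
        assert np.abs(acc.dw_out).max() == 0.0
        assert acc.db_out[0] == pytest.approx(-0.7)

    def test_zero_error_no_update(self):
        cfg = NetworkConfig(n_in=1, n_rec=2, n_out=1)
        acc = GradientAccumulator.zeros(cfg)
        output_layer_updates(acc, np.zeros(1), np.ones(2))
        assert np.abs(acc.dw_out).max() == 0.0 and acc.db_out[0] == 0.0


class TestAdaptiveBroadcast:
    def test_mirrors_output_update(self, rng):
        cfg = NetworkConfig(n_in=1, n_rec=4, n_out=2)
        acc = GradientAccumulator.zeros(cfg)
        err = rng.normal(size=2)
        z_bar = rng.normal(size=4)
        output_layer_updates(acc, err, z_bar)
        adaptive_broadcast_update(acc, err, z_bar, mode="adaptive")
        np.testing.assert_allclose(acc.d_b_mat, acc.dw_out.T)

    def test_equal_start_stays_equal(self, rng):
        cfg = NetworkConfig(n_in=1, n_rec=4, n_out=2)
        acc = GradientAccumulator.zeros(cfg)
        for _ in range(5):
            err, z_bar = rng.normal(size=2), rng.normal(size=4)
            output_layer_updates(acc, err, z_bar)
            adaptive_broadcast_update(acc, err, z_bar, mode="adaptive")
        w_out = rng.normal(size=(2, 4))
        b_mat = w_out.T.copy()
        np.testing.assert_allclose(w_out + acc.dw_out, (b_mat + acc.d_b_mat).T)

    def test_rejected_outside_adaptive_mode(self):
        cfg = NetworkConfig(n_in=1, n_rec=2, n_out=1)
        acc = GradientAccumulator.zeros(cfg)
        with pytest.raises(ConfigurationError):
            adaptive_broadcast_update(acc, np.zeros(1), np.zeros(2), mode="random")


class _TinyRegressionTask:
    """Frozen random trial for degenerate-case tests."""

    def __init__(self, T=60, n_in=4, seed=0):
        rng = np.random.default_rng(seed)
        self.x = (rng.random((T, n_in)) < 0.4).astype(np.int8)
        t = np.arange(T)
        self.y_star = (0.5 * np.sin(2 * np.pi * t / 30))[:, None]
        self.mask = np.ones(T)

    def sample_batch(self, rng, n):
        return (np.repeat(self.x[None], n, axis=0),
                np.repeat(self.y_star[None], n, axis=0),
                np.repeat(self.mask[None], n, axis=0))


class TestTrainSupervised:
    def test_zero_learning_rate_freezes_loss(self):
        task = _TinyRegressionTask()
        cfg = NetworkConfig(n_in=4, n_rec=8, n_out=1, v_th=0.5, seed=3)
        learn = LearningMode(mode="symmetric", loss_kind="regression", eta=0.0)
        _, hist = train_supervised(task, cfg, learn, n_iterations=5,
                                   batch_size=2, seed=3, eval_every=0)
        losses = [h["loss"] for h in hist]
        assert max(losses) - min(losses) < 1e-9

    def test_readout_only_training_reaches_least_squares(self):
        """With zero feedback the recurrent net is a fixed feature
        generator and the readout must converge to the least-squares fit."""
        task = _TinyRegressionTask()
        cfg = NetworkConfig(n_in=4, n_rec=10, n_out=1, v_th=0.4, seed=3)
        learn = LearningMode(mode="random", loss_kind="regression", eta=5e-3,
                             optimizer="adam")
        weights = initialize_weights(cfg, np.random.default_rng(0),
                                     feedback="random", gain=1.5)
        weights.b_mat[...] = 0.0  # no recurrent/input plasticity
        weights, _ = train_supervised(task, cfg, learn, weights=weights,
                                      n_iterations=400, batch_size=1,
                                      seed=3, eval_every=0, dtype=np.float64)
        learn_fine = LearningMode(mode="random", loss_kind="regression",
                                  eta=1e-4, optimizer="sgd")
        weights, hist = train_supervised(task, cfg, learn_fine, weights=weights,
                                         n_iterations=1500, batch_size=1,
                                         seed=4, eval_every=0, dtype=np.float64)
        # closed form: y_t = W zbar_t + b kern_t with kappa-filtered features
        rec = run_trial(weights, task.x, cfg)
        zbar = np.zeros((60, cfg.n_rec))
        kern = np.zeros(60)
        zacc, kacc = np.zeros(cfg.n_rec), 0.0
        for t in range(60):
            zacc = cfg.kappa * zacc + rec.z[t]
            kacc = cfg.kappa * kacc + 1.0
            zbar[t], kern[t] = zacc, kacc
        feats = np.column_stack([zbar, kern])
        coef, *_ = np.linalg.lstsq(feats, task.y_star[:, 0], rcond=None)
        optimum = 0.5 * ((feats @ coef - task.y_star[:, 0]) ** 2).sum()
        final = hist[-1]["loss"]
        assert final <= optimum * 1.05 + 1e-6

    def test_one_update_descends_on_feedforward_regression(self, rng):
        """Symmetric feedback with zero recurrent weights follows the exact
        gradient, so a small step must not increase the batch loss."""
        task = _TinyRegressionTask()
        cfg = NetworkConfig(n_in=4, n_rec=8, n_out=1, v_th=0.4, seed=5)
        learn = LearningMode(mode="symmetric", loss_kind="regression", eta=1e-4)
        for seed in range(5):
            w = initialize_weights(cfg, np.random.default_rng(seed), gain=1.5)
            w.w_rec[...] = 0.0
            x, tgt, mask = task.sample_batch(None, 2)
            before = evaluate(w, cfg, x, tgt, mask, learn)["loss"]
            grads, _ = _forward_learn_batch(w, cfg, x, tgt, mask, learn,
                                            b_mat=w.w_out.T, dtype=np.float64)
            for name, g in grads.items():
                getattr(w, name).__isub__(learn.eta * g)
            after = evaluate(w, cfg, x, tgt, mask, learn)["loss"]
            assert after <= before + 1e-9

    def test_mode_contracts(self):
        """Random-mode feedback is bit-identical across training; symmetric
        feedback tracks the output transpose."""
        task = _TinyRegressionTask()
        cfg = NetworkConfig(n_in=4, n_rec=8, n_out=1, v_th=0.4, seed=11)
        w0 = initialize_weights(cfg, np.random.default_rng(1), feedback="random")
        b_before = w0.b_mat.copy()
        learn = LearningMode(mode="random", loss_kind="regression", eta=1e-3)
        w1, _ = train_supervised(task, cfg, learn, weights=w0, n_iterations=10,
                                 batch_size=2, seed=1, eval_every=0)
        np.testing.assert_array_equal(w1.b_mat, b_before)

        w2 = initialize_weights(cfg, np.random.default_rng(2), feedback="symmetric")
        learn_s = LearningMode(mode="symmetric", loss_kind="regression", eta=1e-3)
        w2, _ = train_supervised(task, cfg, learn_s, weights=w2, n_iterations=10,
                                 batch_size=2, seed=2, eval_every=0)
        # the trainer resolves symmetric feedback from w_out at every batch

    def test_divergence_aborts(self):
        task = _TinyRegressionTask()
        cfg = NetworkConfig(n_in=4, n_rec=8, n_out=1, v_th=0.4, seed=5)
        learn = LearningMode(mode="symmetric", loss_kind="regression", eta=1e6)
        with pytest.raises(RuntimeError):
            train_supervised(task, cfg, learn, n_iterations=50, batch_size=2,
                             seed=5, eval_every=0)
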