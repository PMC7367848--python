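"""Unit and property tests for the LIF/ALIF network simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eprop import (ConfigurationError, NetworkConfig, NeuronState,
                   SynapticWeights, alif_step, decay_constants,
                   initialize_weights, lif_step, pseudo_derivative,
                   readout_step, run_trial)
from eprop.dynamics import StructuralError

from conftest import random_spikes


def _config(**kw):
    base = dict(n_in=1, n_rec=1, n_out=1)
    base.update(kw)
    return NetworkConfig(**base)


class TestDecayConstants:
    def test_printed_formula(self):
        cfg = _config(tau_m=20.0, tau_a=1e10, tau_out=1.0)
        alpha, rho, kappa = decay_constants(cfg)
        assert alpha == pytest.approx(0.951229, abs=1e-6)
        assert rho > 0.999999999  # tau_a -> infinity limit
        assert kappa == pytest.approx(0.367879, abs=1e-6)
        assert all(0 < c < 1 for c in (alpha, rho, kappa))

    def test_invalid_tau_rejected(self):
        with pytest.raises(ConfigurationError):
            _config(tau_m=-5.0)
        with pytest.raises(ConfigurationError):
            _config(dt=0.0)


def _single_neuron(w_in=0.0, w_out=1.0, **cfg_kw):
    cfg = _config(**cfg_kw)
    w = SynapticWeights(np.array([[w_in]]), np.zeros((1, 1)),
                        np.array([[w_out]]), np.zeros(1), np.array([[w_out]]))
    return cfg, w


class TestLifStep:
    def test_integration_reaches_threshold(self):
        # alpha = 0.5: v' = 0.5*0.8 + 0.6 = 1.0 >= v_th = 1 -> spike
        cfg, w = _single_neuron(w_in=0.6, tau_m=1 / math.log(2), v_th=1.0,
                                n_refractory=0)
        state = NeuronState.zeros(cfg)
        state.v[:] = 0.8
        new = lif_step(state, np.array([1.0]), w, cfg)
        assert new.v[0] == pytest.approx(1.0)
        assert new.z[0] == 1.0

    def test_reset_subtracts_threshold(self):
        cfg, w = _single_neuron(tau_m=1 / math.log(2), v_th=1.0, n_refractory=0)
        state = NeuronState.zeros(cfg)
        state.v[:] = 1.0
        state.z[:] = 1.0  # spiked last step
        new = lif_step(state, np.array([0.0]), w, cfg)
        assert new.v[0] == pytest.approx(0.5 * 1.0 - 1.0)
        assert new.z[0] == 0.0

    def test_zero_input_fixed_point(self):
        cfg, w = _single_neuron()
        state = NeuronState.zeros(cfg)
        for _ in range(10):
            state = lif_step(state, np.array([0.0]), w, cfg)
        assert state.v[0] == 0.0 and state.z[0] == 0.0

    def test_dimension_mismatch(self, small_config, small_weights):
        state = NeuronState.zeros(small_config)
        with pytest.raises(StructuralError):
            alif_step(state, np.zeros(small_config.n_in + 1),
                      small_weights, small_config)


class TestAlifStep:
    def test_beta_zero_matches_lif(self, rng):
        cfg_alif = NetworkConfig(n_in=2, n_rec=4, n_out=1, n_adaptive=4,
                                 beta=0.0, v_th=0.4, tau_a=100.0)
        w = initialize_weights(cfg_alif, rng, gain=1.5)
        x = random_spikes(rng, 30, 2)
        rec_alif = run_trial(w, x, cfg_alif)
        rec_lif = run_trial(w, x, cfg_alif.with_(n_adaptive=0))
        np.testing.assert_array_equal(rec_alif.v, rec_lif.v)
        np.testing.assert_array_equal(rec_alif.z, rec_lif.z)
        np.testing.assert_array_equal(rec_alif.psi, rec_lif.psi)

    def test_adaptation_decay_and_jump(self):
        # rho = 0.9, a = 1, z = 0 -> a' = 0.9, threshold v_th + 0.9*beta
        cfg = NetworkConfig(n_in=1, n_rec=1, n_out=1, n_adaptive=1,
                            tau_a=1 / -math.log(0.9), beta=0.5, v_th=1.0)
        w = SynapticWeights(np.zeros((1, 1)), np.zeros((1, 1)),
                            np.ones((1, 1)), np.zeros(1), np.ones((1, 1)))
        state = NeuronState.zeros(cfg)
        state.a[:] = 1.0
        new = alif_step(state, np.array([0.0]), w, cfg)
        assert new.a[0] == pytest.approx(0.9)
        # spike raises the threshold by beta on the next step
        state2 = NeuronState.zeros(cfg)
        state2.z[:] = 1.0
        new2 = alif_step(state2, np.array([0.0]), w, cfg)
        assert new2.a[0] == pytest.approx(1.0)


class TestPseudoDerivative:
    def test_at_threshold(self):
        cfg = _config(v_th=1.0, gamma_pd=0.3)
        psi = pseudo_derivative(np.array([1.0]), np.array([1.0]),
                                np.array([0]), cfg)
        assert psi[0] == pytest.approx(0.3)

    def test_clamped_far_from_threshold(self):
        cfg = _config(v_th=1.0, gamma_pd=0.3)
        psi = pseudo_derivative(np.array([-0.5, 2.5]), np.array([1.0, 1.0]),
                                np.array([0, 0]), cfg)
        assert (psi == 0).all()

    def test_zero_during_refractoriness(self):
        cfg = _config(v_th=1.0, gamma_pd=0.3)
        psi = pseudo_derivative(np.array([1.0]), np.array([1.0]),
                                np.array([2]), cfg)
        assert psi[0] == 0.0


class TestReadout:
    def test_leaky_accumulation(self):
        cfg = _config(tau_out=1 / math.log(2))  # kappa = 0.5
        w = SynapticWeights(np.zeros((1, 1)), np.zeros((1, 1)),
                            np.array([[0.3]]), np.zeros(1), np.array([[0.3]]))
        y = readout_step(np.array([0.2]), np.array([1.0]), w, cfg)
        assert y[0] == pytest.approx(0.4)

    def test_geometric_decay_without_spikes(self):
        cfg = _config(tau_out=10.0)
        w = SynapticWeights(np.zeros((1, 1)), np.zeros((1, 1)),
                            np.ones((1, 1)), np.zeros(1), np.ones((1, 1)))
        y = np.array([1.0])
        for t in range(1, 6):
            y = readout_step(y, np.array([0.0]), w, cfg)
            assert y[0] == pytest.approx(cfg.kappa ** t)


class TestRunTrial:
    def test_replay_is_bit_identical(self, small_config, small_weights, rng):
        x = random_spikes(rng, 40, small_config.n_in)
        r1 = run_trial(small_weights, x, small_config)
        r2 = run_trial(small_weights, x, small_config)
        for name in ("v", "a", "z", "psi", "y"):
            np.testing.assert_array_equal(getattr(r1, name), getattr(r2, name))

    def test_replay_through_step_ops(self, small_config, small_weights, rng):
        """The recording must be reproducible by the public step operations."""
        x = random_spikes(rng, 25, small_config.n_in)
        rec = run_trial(small_weights, x, small_config)
        state = NeuronState.zeros(small_config)
        y = np.zeros(small_config.n_out)
        for t in range(25):
            z_pre = rec.z[t - 1] if t >= 1 else np.zeros(small_config.n_rec)
            state = alif_step(state, x[t].astype(float), small_weights,
                              small_config, z_pre=z_pre)
            y = readout_step(y, state.z, small_weights, small_config)
            np.testing.assert_array_equal(state.v, rec.v[t])
            np.testing.assert_array_equal(state.z, rec.z[t])
            np.testing.assert_array_equal(y, rec.y[t])

    def test_single_spike_then_refractory_silence(self):
        cfg = NetworkConfig(n_in=1, n_rec=1, n_out=1, n_refractory=2,
                            v_th=1.0, tau_m=1 / math.log(2))  # alpha = 0.5
        w = SynapticWeights(np.array([[5.0]]), np.zeros((1, 1)),
                            np.ones((1, 1)), np.zeros(1), np.ones((1, 1)))
        x = np.zeros((8, 1), dtype=np.int8)
        x[1, 0] = 1
        rec = run_trial(w, x, cfg)
        assert rec.z[1, 0] == 1.0
        # at t = 2 the membrane is still above threshold (0.5*5 - 1 = 1.5)
        # but the refractory countdown forces silence and psi = 0
        assert rec.v[2, 0] >= cfg.v_th
        assert (rec.z[2:4, 0] == 0).all()
        assert (rec.psi[2:4, 0] == 0).all()
        assert rec.z.sum() == 1.0

    def test_empty_trial(self, small_config, small_weights):
        rec = run_trial(small_weights, np.zeros((0, small_config.n_in)),
                        small_config)
        assert rec.n_steps == 0

    def test_nonbinary_input_rejected(self, small_config, small_weights):
        with pytest.raises(ValueError):
            run_trial(small_weights, np.full((5, small_config.n_in), 0.5),
                      small_config)

    def test_membrane_linearity_below_threshold(self, rng):
        """With no spikes, the membrane response obeys superposition."""
        cfg = NetworkConfig(n_in=2, n_rec=3, n_out=1, v_th=100.0)  # never fires
        w = initialize_weights(cfg, rng, gain=1.0)
        x1 = random_spikes(rng, 20, 2)
        x2 = random_spikes(rng, 20, 2)
        both = np.clip(x1 + x2, 0, 1)
        overlap = (x1 & x2).astype(np.int8)
        v_sum = (run_trial(w, x1, cfg).v + run_trial(w, x2, cfg).v
                 - run_trial(w, overlap, cfg).v)
        np.testing.assert_allclose(run_trial(w, both, cfg).v, v_sum, atol=1e-12)


class TestWeightInvariants:
    def test_recurrent_diagonal_zero(self, rng):
        cfg = NetworkConfig(n_in=2, n_rec=5, n_out=1)
        w = initialize_weights(cfg, rng)
        assert (np.diag(w.w_rec) == 0).all()

    def test_symmetric_feedback_is_transpose(self, rng):
        cfg = NetworkConfig(n_in=2, n_rec=5, n_out=2)
        w = initialize_weights(cfg, rng, feedback="symmetric")
        np.testing.assert_array_equal(w.b_mat, w.w_out.T)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_ref=st.integers(0, 4))
def test_spike_binarity_and_refractory_silencing(seed, n_ref):
    """For arbitrary weights/inputs, spikes are binary and every spike is
    followed by at least n_refractory silent steps."""
    rng = np.random.default_rng(seed)
    cfg = NetworkConfig(n_in=3, n_rec=5, n_out=1, n_adaptive=2,
                        v_th=0.3, n_refractory=n_ref, tau_a=50.0)
    w = initialize_weights(cfg, rng, gain=2.0)
    x = (rng.random((30, 3)) < 0.5).astype(np.int8)
    rec = run_trial(w, x, cfg)
    assert np.isin(rec.z, (0.0, 1.0)).all()
    T = rec.n_steps
    for t, j in zip(*np.nonzero(rec.z)):
        assert rec.z[t + 1:min(t + 1 + n_ref, T), j].sum() == 0
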