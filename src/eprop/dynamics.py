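"""Discrete-time simulation of recurrent LIF/ALIF networks with leaky readouts.

The network state is advanced in steps of ``dt``.  At each step the
membrane potential integrates weighted presynaptic spikes with exponential
leak ``alpha`` and is reduced by ``v_th`` after an own spike (soft reset);
adapting neurons additionally carry a threshold offset ``a`` that jumps by
one per spike and decays with ``rho``.  Spikes are binary; a neuron is
silenced (and its surrogate derivative zeroed) for ``n_refractory`` steps
after firing.  Readouts are non-spiking leaky integrators of the weighted
spike trains.

Everything needed for learning and for gradient verification (membrane
potentials, adaptation variables, spikes, surrogate derivatives, readouts)
is recorded per step in a :class:`TrialRecording`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import ConfigurationError, NetworkConfig


class StructuralError(ValueError):
    """Raised on shape mismatches between states, weights, and config."""


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------

@dataclass
class SynapticWeights:
    """Input, recurrent, and output weights plus the broadcast matrix.

    ``w_rec`` has an identically zero diagonal (no self-connections).
    ``b_mat`` holds the feedback (broadcast) weights that route readout
    errors back to the recurrent neurons: one column per readout.  In
    symmetric feedback mode it equals ``w_out.T`` at all times.
    """

    w_in: np.ndarray   # (n_rec, n_in)
    w_rec: np.ndarray  # (n_rec, n_rec), zero diagonal
    w_out: np.ndarray  # (n_out, n_rec)
    b_out: np.ndarray  # (n_out,)
    b_mat: np.ndarray  # (n_rec, n_out)

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.w_rec = np.asarray(self.w_rec, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        self.b_out = np.asarray(self.b_out, dtype=float)
        self.b_mat = np.asarray(self.b_mat, dtype=float)
        n_rec = self.w_rec.shape[0]
        if self.w_rec.shape != (n_rec, n_rec):
            raise StructuralError(f"w_rec must be square, got {self.w_rec.shape}")
        if self.w_in.shape[0] != n_rec:
            raise StructuralError("w_in rows must match n_rec")
        if self.w_out.shape[1] != n_rec or self.b_mat.shape[0] != n_rec:
            raise StructuralError("w_out / b_mat must match n_rec")
        if self.b_out.shape != (self.w_out.shape[0],):
            raise StructuralError("b_out must have one entry per readout")
        np.fill_diagonal(self.w_rec, 0.0)

    def check_against(self, config: NetworkConfig) -> None:
        if self.w_in.shape != (config.n_rec, config.n_in):
            raise StructuralError(
                f"w_in shape {self.w_in.shape} != ({config.n_rec}, {config.n_in})")
        if self.w_out.shape != (config.n_out, config.n_rec):
            raise StructuralError(
                f"w_out shape {self.w_out.shape} != ({config.n_out}, {config.n_rec})")

    def copy(self) -> "SynapticWeights":
        return SynapticWeights(self.w_in.copy(), self.w_rec.copy(),
                               self.w_out.copy(), self.b_out.copy(),
                               self.b_mat.copy())


def initialize_weights(config: NetworkConfig,
                       rng: np.random.Generator | None = None,
                       feedback: str = "symmetric",
                       gain: float = 1.0) -> SynapticWeights:
    """Draw zero-mean Gaussian weights with std ``gain / sqrt(fan_in)``.

    ``feedback`` selects how the broadcast matrix is set up: ``symmetric``
    ties it to ``w_out.T``; ``random`` and ``adaptive`` draw it
    independently with the same statistics as ``w_out``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_in, n_rec, n_out = config.n_in, config.n_rec, config.n_out
    w_in = rng.normal(0.0, gain / np.sqrt(max(n_in, 1)), size=(n_rec, n_in))
    w_rec = rng.normal(0.0, gain / np.sqrt(n_rec), size=(n_rec, n_rec))
    np.fill_diagonal(w_rec, 0.0)
    w_out = rng.normal(0.0, gain / np.sqrt(n_rec), size=(n_out, n_rec))
    b_out = np.zeros(n_out)
    if feedback == "symmetric":
        b_mat = w_out.T.copy()
    elif feedback in ("random", "adaptive"):
        b_mat = rng.normal(0.0, gain / np.sqrt(n_rec), size=(n_rec, n_out))
    else:
        raise ConfigurationError(f"unknown feedback mode {feedback!r}")
    return SynapticWeights(w_in, w_rec, w_out, b_out, b_mat)


# ---------------------------------------------------------------------------
# Neuron state and single-step operations
# ---------------------------------------------------------------------------

@dataclass
class NeuronState:
    """Instantaneous state of the recurrent population.

    ``v``: membrane potentials; ``a``: threshold adaptation (zero for LIF
    rows); ``r``: refractory countdown in steps; ``z``: spikes emitted this
    step; ``psi``: surrogate (pseudo-) derivative at this step, already
    zeroed for refractory neurons.  Arrays may carry leading batch axes.
    """

    v: np.ndarray
    a: np.ndarray
    r: np.ndarray
    z: np.ndarray
    psi: np.ndarray

    @classmethod
    def zeros(cls, config: NetworkConfig, batch_shape: tuple = (),
              dtype=np.float64) -> "NeuronState":
        shape = (*batch_shape, config.n_rec)
        return cls(
            v=np.full(shape, config.v0, dtype=dtype),
            a=np.full(shape, config.a0, dtype=dtype),
            r=np.zeros(shape, dtype=np.int64),
            z=np.zeros(shape, dtype=dtype),
            psi=np.zeros(shape, dtype=dtype),
        )


def pseudo_derivative(v: np.ndarray, A: np.ndarray, r: np.ndarray,
                      config: NetworkConfig) -> np.ndarray:
    """Triangular surrogate derivative of the spike threshold function.

    ``psi = gamma_pd/v_th * max(0, 1 - |v - A| / v_th)`` outside the
    refractory period, and exactly 0 where the countdown ``r`` is positive.
    For LIF neurons the threshold ``A`` is the constant ``v_th``.
    """
    v_th = config.v_th
    psi = (config.gamma_pd / v_th) * np.maximum(0.0, 1.0 - np.abs((v - A) / v_th))
    return np.where(r > 0, 0.0, psi)


def threshold(state_a: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """Effective firing threshold ``A = v_th + beta * a`` (per neuron)."""
    beta_vec = config.beta_vector(dtype=np.asarray(state_a).dtype)
    return config.v_th + beta_vec * state_a


def alif_step(state: NeuronState, x_next: np.ndarray, weights: SynapticWeights,
              config: NetworkConfig, z_pre: np.ndarray | None = None) -> NeuronState:
    """Advance the (possibly mixed LIF/ALIF) population by one step.

    The membrane integrates the previous step's recurrent spikes (or the
    delayed spikes ``z_pre`` if given), the incoming input spikes
    ``x_next``, and subtracts ``v_th`` once per own spike of the previous
    step.  Adapting rows update ``a' = rho*a + z`` and fire against the
    dynamic threshold ``v_th + beta*a'``; LIF rows fire against ``v_th``.
    Spiking starts a refractory countdown of ``n_refractory`` steps during
    which the spike output and surrogate derivative are forced to zero.
    """
    x_next = np.asarray(x_next)
    if x_next.shape[-1] != config.n_in:
        raise StructuralError(f"input has {x_next.shape[-1]} channels, expected {config.n_in}")
    if state.v.shape[-1] != config.n_rec:
        raise StructuralError("state does not match n_rec")
    weights.check_against(config)
    if z_pre is None:
        z_pre = state.z

    dtype = state.v.dtype
    alpha = dtype.type(config.alpha)
    rho = dtype.type(config.rho)
    v_th = dtype.type(config.v_th)
    beta_vec = config.beta_vector(dtype=dtype)
    adaptive = np.zeros(config.n_rec, dtype=dtype)
    adaptive[config.n_regular:] = 1

    v_new = (alpha * state.v
             + z_pre @ weights.w_rec.T.astype(dtype)
             + x_next.astype(dtype) @ weights.w_in.T.astype(dtype)
             - state.z * v_th)
    a_new = (rho * state.a + state.z) * adaptive
    A_new = v_th + beta_vec * a_new

    refractory = state.r > 0
    fired = (v_new - A_new >= 0) & ~refractory
    z_new = fired.astype(dtype)
    psi_new = pseudo_derivative(v_new, A_new, state.r, config)
    r_new = np.where(fired, config.n_refractory,
                     np.maximum(state.r - 1, 0)).astype(np.int64)
    return NeuronState(v=v_new, a=a_new, r=r_new, z=z_new, psi=psi_new)


def lif_step(state: NeuronState, x_next: np.ndarray, weights: SynapticWeights,
             config: NetworkConfig, z_pre: np.ndarray | None = None) -> NeuronState:
    """LIF-only step: every neuron fires against the constant threshold."""
    return alif_step(state, x_next, weights, config.with_(n_adaptive=0), z_pre=z_pre)


def readout_step(y_prev: np.ndarray, z: np.ndarray, weights: SynapticWeights,
                 config: NetworkConfig) -> np.ndarray:
    """Leaky readout update ``y = kappa*y_prev + w_out @ z + b_out``."""
    dtype = np.asarray(y_prev).dtype
    kappa = np.asarray(config.kappa, dtype=dtype)
    return kappa * y_prev + z @ weights.w_out.T.astype(dtype) + weights.b_out.astype(dtype)


# ---------------------------------------------------------------------------
# Whole-trial simulation
# ---------------------------------------------------------------------------

@dataclass
class TrialRecording:
    """Complete forward-pass history of one trial (or a batch of trials).

    Arrays are indexed ``[t, ...]`` (or ``[batch, t, ...]``): ``x`` input
    spikes, ``v``/``a``/``z``/``psi`` recurrent histories, ``y`` readouts,
    and a per-step ``loss_mask`` in [0, 1].  Replaying ``x`` through the
    step operations reproduces every array bit-identically.
    """

    x: np.ndarray
    v: np.ndarray
    a: np.ndarray
    z: np.ndarray
    psi: np.ndarray
    y: np.ndarray
    loss_mask: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.x.shape[-2]

    @property
    def batched(self) -> bool:
        return self.x.ndim == 3

    def save(self, path) -> None:
        np.savez(path, x=self.x, v=self.v, a=self.a, z=self.z,
                 psi=self.psi, y=self.y, loss_mask=self.loss_mask)

    @classmethod
    def load(cls, path) -> "TrialRecording":
        with np.load(path) as data:
            return cls(**{k: data[k] for k in
                          ("x", "v", "a", "z", "psi", "y", "loss_mask")})


def run_trial(weights: SynapticWeights, x: np.ndarray, config: NetworkConfig,
              loss_mask: np.ndarray | None = None,
              dtype=np.float64) -> TrialRecording:
    """Simulate a full trial (deterministically) and record every step.

    ``x`` is a binary spike tensor of shape ``(T, n_in)`` or, for a batch
    of trials, ``(batch, T, n_in)``.  The initial state is given by the
    configuration (zeros by default).
    """
    x = np.asarray(x)
    if x.ndim == 2:
        rec = run_trial(weights, x[None], config,
                        None if loss_mask is None else np.asarray(loss_mask)[None],
                        dtype=dtype)
        return TrialRecording(**{k: getattr(rec, k)[0] for k in
                                 ("x", "v", "a", "z", "psi", "y", "loss_mask")})
    if x.ndim != 3 or x.shape[-1] != config.n_in:
        raise StructuralError(f"x must be (T, n_in) or (batch, T, n_in); got {x.shape}")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("input spikes must be binary")
    weights.check_against(config)

    batch, T, _ = x.shape
    if loss_mask is None:
        loss_mask = np.ones((batch, T), dtype=dtype)
    loss_mask = np.asarray(loss_mask, dtype=dtype)

    state = NeuronState.zeros(config, batch_shape=(batch,), dtype=dtype)
    y = np.full((batch, config.n_out), config.y0, dtype=dtype)

    v_h = np.empty((batch, T, config.n_rec), dtype=dtype)
    a_h = np.empty_like(v_h)
    z_h = np.empty_like(v_h)
    psi_h = np.empty_like(v_h)
    y_h = np.empty((batch, T, config.n_out), dtype=dtype)

    xd = x.astype(dtype)
    zero_z = np.zeros((batch, config.n_rec), dtype=dtype)
    for t in range(T):
        # transmission delay: recurrent spikes from t - delay arrive now
        td = t - config.delay
        z_pre = z_h[:, td] if td >= 0 else zero_z
        state = alif_step(state, xd[:, t], weights, config, z_pre=z_pre)
        y = readout_step(y, state.z, weights, config)
        v_h[:, t] = state.v
        a_h[:, t] = state.a
        z_h[:, t] = state.z
        psi_h[:, t] = state.psi
        y_h[:, t] = y

    return TrialRecording(x=x, v=v_h, a=a_h, z=z_h, psi=psi_h, y=y_h,
                          loss_mask=loss_mask)


# ---------------------------------------------------------------------------
# Relaxed (smooth) forward pass for finite-difference gradient checks
# ---------------------------------------------------------------------------

def _smooth_spike(u: np.ndarray, config: NetworkConfig) -> np.ndarray:
    """Antiderivative of the triangular surrogate, scaled like psi.

    A continuous "spike amplitude" whose derivative w.r.t. ``u = v - A`` is
    exactly the triangular pseudo-derivative.  Used only to build a smooth
    stand-in network on which finite differences are valid.
    """
    g, vt = config.gamma_pd, config.v_th
    u = np.asarray(u, dtype=float)
    un = np.clip(u / vt, -1.0, 1.0)
    # integral of (g/vt) * (1 - |u|/vt) from -vt to u
    val = (g / 2.0) * np.where(un <= 0, (1.0 + un) ** 2, 1.0 + un * (2.0 - un))
    return np.where(u <= -vt, 0.0, np.where(u >= vt, g, val))


def run_relaxed_trial(weights: SynapticWeights, x: np.ndarray,
                      config: NetworkConfig,
                      loss_mask: np.ndarray | None = None) -> TrialRecording:
    """Forward pass of the smooth surrogate network (for gradient checks).

    Spikes are replaced by the continuous amplitude ``sigma(v - A)`` whose
    derivative is the triangular pseudo-derivative; there is no reset and
    no refractoriness.  On this system the unrolled computation is
    differentiable, so the backward-pass gradients can be validated with
    central finite differences.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
        if loss_mask is not None:
            loss_mask = np.asarray(loss_mask)[None]
    batch, T, _ = x.shape
    if loss_mask is None:
        loss_mask = np.ones((batch, T))
    loss_mask = np.asarray(loss_mask, dtype=float)

    beta_vec = config.beta_vector()
    adaptive = (beta_vec > 0) | (np.arange(config.n_rec) >= config.n_regular)
    v = np.zeros((batch, config.n_rec))
    a = np.zeros_like(v)
    z = np.zeros_like(v)
    y = np.zeros((batch, config.n_out))
    v_h = np.empty((batch, T, config.n_rec))
    a_h = np.empty_like(v_h)
    z_h = np.empty_like(v_h)
    psi_h = np.empty_like(v_h)
    y_h = np.empty((batch, T, config.n_out))
    zero_r = np.zeros(config.n_rec, dtype=np.int64)

    for t in range(T):
        td = t - config.delay
        z_pre = z_h[:, td] if td >= 0 else np.zeros_like(z)
        v = config.alpha * v + z_pre @ weights.w_rec.T + x[:, t] @ weights.w_in.T
        a = (config.rho * a + z) * adaptive
        A = config.v_th + beta_vec * a
        z = _smooth_spike(v - A, config)
        y = config.kappa * y + z @ weights.w_out.T + weights.b_out
        v_h[:, t] = v
        a_h[:, t] = a
        z_h[:, t] = z
        psi_h[:, t] = pseudo_derivative(v, A, zero_r, config)
        y_h[:, t] = y

    rec = TrialRecording(x=x, v=v_h, a=a_h, z=z_h, psi=psi_h, y=y_h,
                         loss_mask=loss_mask)
    if single:
        rec = TrialRecording(**{k: getattr(rec, k)[0] for k in
                                ("x", "v", "a", "z", "psi", "y", "loss_mask")})
    return rec
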