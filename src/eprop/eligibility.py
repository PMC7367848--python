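"""Forward-in-time eligibility vectors and traces for LIF and ALIF synapses.

The eligibility vector of a synapse collects, during the forward pass, the
product-sum of within-neuron state Jacobians applied to the direct weight
sensitivity of the hidden state.  For LIF synapses it reduces to the
membrane-filtered presynaptic spike train; ALIF synapses carry a second,
slow component that decays with the adaptation time constant and underlies
the long temporal reach of the learning rule.

Index contract (the brute-force evaluator below is the arbiter): with
recording arrays indexed ``t = 0..T-1``,

* recurrent synapses:  ``eps_v[t] = alpha*eps_v[t-1] + z[t-delay]``
* input synapses:      ``eps_v[t] = alpha*eps_v[t-1] + x[t]``
* ``eps_a[t] = psi[t-1]*eps_v[t-1] + (rho - psi[t-1]*beta)*eps_a[t-1]``
* trace ``e[t] = psi[t] * (eps_v[t] - beta*eps_a[t])``

with all state zero before ``t = 0``.  ``eps_v`` depends only on the
presynaptic unit and is therefore stored once per presynaptic channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, NetworkConfig
from .dynamics import StructuralError, SynapticWeights, TrialRecording

__all__ = [
    "EligibilityState", "low_pass", "lif_eligibility_step",
    "alif_eligibility_step", "simplified_alif_trace_step",
    "eligibility_history", "presynaptic_history", "brute_force_eligibility",
]


def low_pass(prev: np.ndarray, x: np.ndarray, decay: float) -> np.ndarray:
    """One step of the exponential low-pass filter ``F(x) = decay*F + x``.

    With the convention that the filter of the first sample is the sample
    itself (initialize ``prev = 0``).
    """
    if not 0.0 <= decay <= 1.0:
        raise ConfigurationError(f"filter decay {decay} outside [0, 1]")
    return decay * prev + x


@dataclass
class EligibilityState:
    """Per-synapse eligibility quantities for one weight block.

    ``eps_v``: membrane component, one value per presynaptic unit
    (postsynaptic-independent).  ``eps_a``: slow adaptation component,
    shape ``(..., n_rec, n_pre)``, identically zero for LIF rows.
    ``e``: eligibility trace; ``e_bar``: its readout-filtered version.
    """

    eps_v: np.ndarray   # (..., n_pre)
    eps_a: np.ndarray   # (..., n_rec, n_pre)
    e: np.ndarray       # (..., n_rec, n_pre)
    e_bar: np.ndarray   # (..., n_rec, n_pre)
    psi_prev: np.ndarray  # (..., n_rec) — postsynaptic psi of the previous step
    eps_v_prev: np.ndarray  # (..., n_pre)

    @classmethod
    def zeros(cls, config: NetworkConfig, n_pre: int, batch_shape: tuple = (),
              dtype=np.float64) -> "EligibilityState":
        pre = np.zeros((*batch_shape, n_pre), dtype=dtype)
        syn = np.zeros((*batch_shape, config.n_rec, n_pre), dtype=dtype)
        post = np.zeros((*batch_shape, config.n_rec), dtype=dtype)
        return cls(eps_v=pre, eps_a=syn, e=syn.copy(), e_bar=syn.copy(),
                   psi_prev=post, eps_v_prev=pre.copy())


def _advance(state: EligibilityState, z_pre: np.ndarray, psi: np.ndarray,
             config: NetworkConfig, simplified: bool) -> EligibilityState:
    if z_pre.shape[-1] != state.eps_v.shape[-1]:
        raise StructuralError("presynaptic spike vector does not match eps_v width")
    dtype = state.eps_v.dtype
    alpha = dtype.type(config.alpha)
    rho = dtype.type(config.rho)
    kappa = dtype.type(config.kappa)
    beta_col = config.beta_vector(dtype=dtype)[:, None]

    adaptive_col = np.zeros((config.n_rec, 1), dtype=dtype)
    adaptive_col[config.n_regular:] = 1

    eps_v = alpha * state.eps_v + z_pre
    psi_c = state.psi_prev[..., :, None]
    drive = psi_c * state.eps_v_prev[..., None, :]
    if simplified:
        eps_a = rho * state.eps_a + drive
    else:
        eps_a = (rho - psi_c * beta_col) * state.eps_a + drive
    eps_a = eps_a * adaptive_col  # slow component exists only for ALIF rows
    e = psi[..., :, None] * (eps_v[..., None, :] - beta_col * eps_a)
    e_bar = low_pass(state.e_bar, e, float(kappa))
    return EligibilityState(eps_v=eps_v, eps_a=eps_a, e=e, e_bar=e_bar,
                            psi_prev=psi.copy(), eps_v_prev=eps_v)


def lif_eligibility_step(state: EligibilityState, z_pre: np.ndarray,
                         psi: np.ndarray, config: NetworkConfig) -> EligibilityState:
    """Advance LIF-synapse traces: ``eps_v`` filters the presynaptic train
    and the trace is the product ``psi * eps_v`` (no slow component)."""
    return _advance(state, z_pre, psi, config.with_(n_adaptive=0), simplified=False)


def alif_eligibility_step(state: EligibilityState, z_pre: np.ndarray,
                          psi: np.ndarray, config: NetworkConfig) -> EligibilityState:
    """Advance mixed LIF/ALIF traces with the full slow-component recursion."""
    return _advance(state, z_pre, psi, config, simplified=False)


def simplified_alif_trace_step(state: EligibilityState, z_pre: np.ndarray,
                               psi: np.ndarray, config: NetworkConfig) -> EligibilityState:
    """Advance with the simplified slow component that drops the
    ``-psi*beta`` correction, leaving a plain exponential trace of
    post-pre pairings with the adaptation time constant."""
    return _advance(state, z_pre, psi, config, simplified=True)


def presynaptic_history(recording: TrialRecording, config: NetworkConfig,
                        source: str) -> np.ndarray:
    """Per-step presynaptic spike trains feeding each weight block.

    For recurrent synapses the train is the network spikes delayed by the
    transmission delay; for input synapses it is the input spikes at the
    current step.
    """
    if source == "rec":
        z = recording.z
        d = config.delay
        shifted = np.zeros_like(z)
        if d < z.shape[-2]:
            shifted[..., d:, :] = z[..., :-d, :]
        return shifted
    if source == "in":
        return recording.x.astype(recording.z.dtype)
    raise ConfigurationError(f"unknown synapse source {source!r}")


def eligibility_history(recording: TrialRecording, config: NetworkConfig,
                        source: str = "rec", simplified: bool = False):
    """Compute per-step eligibility quantities for a whole recording.

    Returns ``(eps_v, eps_a, e, e_bar)`` with time as the first
    (post-batch) axis: ``eps_v`` has shape ``(..., T, n_pre)`` and the
    others ``(..., T, n_rec, n_pre)``.
    """
    z_pre = presynaptic_history(recording, config, source)
    psi = recording.psi
    T = recording.n_steps
    n_pre = z_pre.shape[-1]
    batch_shape = psi.shape[:-2]
    state = EligibilityState.zeros(config, n_pre, batch_shape, dtype=psi.dtype)
    eps_v = np.empty((*batch_shape, T, n_pre), dtype=psi.dtype)
    eps_a = np.empty((*batch_shape, T, config.n_rec, n_pre), dtype=psi.dtype)
    e = np.empty_like(eps_a)
    e_bar = np.empty_like(eps_a)
    for t in range(T):
        state = _advance(state, z_pre[..., t, :], psi[..., t, :], config, simplified)
        eps_v[..., t, :] = state.eps_v
        eps_a[..., t, :, :] = state.eps_a
        e[..., t, :, :] = state.e
        e_bar[..., t, :, :] = state.e_bar
    return eps_v, eps_a, e, e_bar


def brute_force_eligibility(recording: TrialRecording, config: NetworkConfig,
                            j: int, i: int, t: int, source: str = "rec") -> float:
    """Evaluate the eligibility trace by its explicit definition.

    Computes the sum over ``t' <= t`` of the chained within-neuron state
    Jacobians applied to the direct weight sensitivity ``[z_pre, 0]``,
    projected through ``dz/dh = [psi, -beta*psi]``.  This is an
    independent, quadratic-time evaluation used as the oracle for the
    recursive updates.
    """
    if recording.batched:
        raise StructuralError("brute-force evaluation expects a single trial")
    T = recording.n_steps
    if not 0 <= t < T:
        raise IndexError(f"step {t} outside [0, {T})")
    z_pre = presynaptic_history(recording, config, source)
    psi = recording.psi
    beta_j = config.beta_vector()[j]
    alpha, rho = config.alpha, config.rho

    def jac(s: int) -> np.ndarray:
        # d h^s / d h^{s-1}; psi of the previous step (zero before t=0)
        p = psi[s - 1, j] if s >= 1 else 0.0
        return np.array([[alpha, 0.0], [p, rho - p * beta_j]])

    eps = np.zeros(2)
    for tp in range(t + 1):
        term = np.array([z_pre[tp, i], 0.0])
        for s in range(tp + 1, t + 1):
            term = jac(s) @ term
        eps += term
    dz_dh = np.array([psi[t, j], -beta_j * psi[t, j]])
    return float(dz_dh @ eps)
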