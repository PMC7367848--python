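"""Exact gradients of the surrogate-differentiable unrolled network.

The backward pass differentiates the unrolled computation graph in which
the spike nonlinearity is replaced by its triangular surrogate derivative
and the post-spike reset is treated as a constant.  It yields the ideal
per-neuron learning signals ``dE/dz_j^t`` (including cross-neuron paths
through the recurrent weights) and reference gradients for every weight
block.  Pairing those ideal signals with the forward-computed eligibility
traces must reproduce the same gradients — that identity is what this
module certifies.

Everything here runs in double precision on complete trial recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NetworkConfig
from .dynamics import (StructuralError, SynapticWeights, TrialRecording,
                       run_relaxed_trial)
from .eligibility import eligibility_history, presynaptic_history
from .losses import loss_value, output_error

__all__ = ["OracleGradients", "backward_pass",
           "eprop_gradient_with_ideal_signal", "finite_difference_check",
           "GradientCheckError"]


class GradientCheckError(RuntimeError):
    """Raised when a finite-difference check is attempted outside the
    certified-smooth regime."""


@dataclass
class OracleGradients:
    """Ideal learning signals and full reference gradients for one trial."""

    dE_dz: np.ndarray    # (T, n_rec) total derivative, incl. cross-neuron paths
    dw_in: np.ndarray    # (n_rec, n_in)
    dw_rec: np.ndarray   # (n_rec, n_rec), zero diagonal
    dw_out: np.ndarray   # (n_out, n_rec)
    db_out: np.ndarray   # (n_out,)


def _filtered_output_errors(recording: TrialRecording, target: np.ndarray,
                            loss_kind: str, kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """Masked per-step output errors and their backward kappa-filter."""
    err = output_error(recording.y, np.asarray(target, dtype=float),
                       recording.loss_mask, loss_kind)
    d_y = np.zeros_like(err)
    acc = np.zeros(err.shape[-1])
    for t in range(err.shape[0] - 1, -1, -1):
        acc = err[t] + kappa * acc
        d_y[t] = acc
    return err, d_y


def backward_pass(recording: TrialRecording, weights: SynapticWeights,
                  config: NetworkConfig, target: np.ndarray,
                  loss_kind: str = "regression") -> OracleGradients:
    """Backpropagate the loss through the unrolled surrogate graph.

    Implements the backward recursion over the two-component hidden state
    ``(v, a)`` with within-neuron Jacobian ``[[alpha, 0],
    [psi, rho - psi*beta]]`` and spike sensitivity ``[psi, -beta*psi]``,
    plus the cross-neuron terms through the recurrent weights at the
    transmission delay.
    """
    if recording.batched:
        raise StructuralError("backward_pass expects a single-trial recording")
    if recording.psi is None:
        raise StructuralError("recording lacks the surrogate-derivative history")
    T = recording.n_steps
    n_rec = config.n_rec
    alpha, rho, kappa = config.alpha, config.rho, config.kappa
    beta_vec = config.beta_vector()
    psi = np.asarray(recording.psi, dtype=float)
    z = np.asarray(recording.z, dtype=float)
    d = config.delay

    err, d_y = _filtered_output_errors(recording, target, loss_kind, kappa)

    dE_dz = np.zeros((T, n_rec))
    g_v = np.zeros((T + 1, n_rec))  # g_v[t] = dE/dv at step t (g_v[T] = 0)
    g_a_next = np.zeros(n_rec)
    for t in range(T - 1, -1, -1):
        L_tot = d_y[t] @ weights.w_out
        if t + d < T:
            L_tot = L_tot + g_v[t + d] @ weights.w_rec
        dE_dz[t] = L_tot
        g_v[t] = psi[t] * L_tot + alpha * g_v[t + 1] + psi[t] * g_a_next
        g_a_next = -beta_vec * psi[t] * L_tot + (rho - psi[t] * beta_vec) * g_a_next

    z_pre = presynaptic_history(recording, config, "rec")
    dw_rec = g_v[:T].T @ z_pre
    np.fill_diagonal(dw_rec, 0.0)
    dw_in = g_v[:T].T @ recording.x.astype(float)
    dw_out = d_y.T @ z
    db_out = d_y.sum(axis=0)
    return OracleGradients(dE_dz=dE_dz, dw_in=dw_in, dw_rec=dw_rec,
                           dw_out=dw_out, db_out=db_out)


def eprop_gradient_with_ideal_signal(recording: TrialRecording,
                                     weights: SynapticWeights,
                                     config: NetworkConfig,
                                     target: np.ndarray,
                                     loss_kind: str = "regression") -> OracleGradients:
    """Sum of (ideal learning signal) x (eligibility trace) over time.

    Uses the forward-computed eligibility traces together with the
    oracle's total derivatives ``dE/dz`` — by the re-factorization
    identity this must equal the backward-pass gradients on every weight
    block.  The readout gradient is computed from the kappa-filtered spike
    train, which is algebraically identical to its backward form.
    """
    oracle = backward_pass(recording, weights, config, target, loss_kind)
    L = oracle.dE_dz
    _, _, e_rec, _ = eligibility_history(recording, config, source="rec")
    _, _, e_in, _ = eligibility_history(recording, config, source="in")
    dw_rec = np.einsum("tj,tji->ji", L, e_rec)
    np.fill_diagonal(dw_rec, 0.0)
    dw_in = np.einsum("tj,tji->ji", L, e_in)

    err, _ = _filtered_output_errors(recording, target, loss_kind, config.kappa)
    z_bar = np.zeros_like(recording.z, dtype=float)
    acc = np.zeros(config.n_rec)
    for t in range(recording.n_steps):
        acc = config.kappa * acc + recording.z[t]
        z_bar[t] = acc
    dw_out = err.T @ z_bar
    # bias enters the readout at every step; its kappa-filtered "trace" is
    # the running geometric kernel F_kappa(1)
    kern = 0.0
    db_out = np.zeros(config.n_out)
    for t in range(recording.n_steps):
        kern = config.kappa * kern + 1.0
        db_out += err[t] * kern
    return OracleGradients(dE_dz=L, dw_in=dw_in, dw_rec=dw_rec,
                           dw_out=dw_out, db_out=db_out)


def finite_difference_check(weights: SynapticWeights, x: np.ndarray,
                            config: NetworkConfig, target: np.ndarray,
                            loss_mask: np.ndarray | None = None,
                            loss_kind: str = "regression",
                            epsilon: float = 1e-5,
                            block: str = "w_in",
                            margin: float = 1e-3,
                            max_entries: int | None = None) -> float:
    """Validate the backward pass with central differences on the smooth net.

    The check runs on the relaxed network (continuous spike amplitudes, no
    reset, no refractoriness), whose unrolled computation is genuinely
    differentiable.  Configurations whose trajectory comes within
    ``margin`` of a kink of the surrogate (a threshold crossing, or the
    saturation edges) are rejected, because finite differences are not
    second-order accurate across them.  Returns the maximum absolute
    deviation between finite differences and the backward-pass gradient
    over the entries of ``block``.
    """
    rec = run_relaxed_trial(weights, x, config, loss_mask)
    u = (rec.v - (config.v_th + config.beta_vector() * rec.a)) / config.v_th
    dist = np.minimum(np.abs(u), np.minimum(np.abs(u - 1), np.abs(u + 1)))
    if dist.min() < margin:
        raise GradientCheckError(
            "trajectory within %g of a surrogate kink (threshold crossing); "
            "finite differences are unreliable here" % margin)

    grads = backward_pass(rec, weights, config, target, loss_kind)
    analytic = getattr(grads, {"w_in": "dw_in", "w_rec": "dw_rec",
                               "w_out": "dw_out", "b_out": "db_out"}[block])
    mat = getattr(weights, block)
    idx = list(np.ndindex(mat.shape))
    if max_entries is not None and len(idx) > max_entries:
        idx = idx[:max_entries]
    worst = 0.0
    for ij in idx:
        if block == "w_rec" and ij[0] == ij[1]:
            continue
        orig = mat[ij]
        mat[ij] = orig + epsilon
        lp = loss_value(run_relaxed_trial(weights, x, config, loss_mask).y,
                        target, rec.loss_mask, loss_kind)
        mat[ij] = orig - epsilon
        lm = loss_value(run_relaxed_trial(weights, x, config, loss_mask).y,
                        target, rec.loss_mask, loss_kind)
        mat[ij] = orig
        fd = (lp - lm) / (2 * epsilon)
        worst = max(worst, abs(fd - analytic[ij]))
    return worst
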