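"""Supervised three-factor learning rules and the training loop.

The weight update for recurrent and input synapses is the product of a
per-neuron learning signal — readout errors routed backwards through a
feedback (broadcast) matrix — with the readout-filtered eligibility trace
of the synapse, accumulated over a batch of trials and applied at batch
boundaries.

Three feedback modes are supported: ``symmetric`` ties the feedback
weights to the transpose of the output weights; ``random`` draws them once
and freezes them (broadcast alignment); ``adaptive`` starts random but
mirrors every output-weight update.  Readout weights and biases follow
their exact gradient in all modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import ConfigurationError, NetworkConfig
from .dynamics import SynapticWeights, pseudo_derivative
from .losses import loss_value, output_error, softmax

__all__ = [
    "LearningMode", "GradientAccumulator", "make_broadcast",
    "regression_learning_signal", "classification_learning_signal",
    "accumulate_recurrent_updates", "output_layer_updates",
    "adaptive_broadcast_update", "train_supervised", "evaluate",
    "Optimizer",
]

FEEDBACK_MODES = ("symmetric", "random", "adaptive")


@dataclass
class LearningMode:
    """Learning-rule configuration for supervised training.

    ``mode``: feedback-weight mode (symmetric / random / adaptive).
    ``loss_kind``: regression or classification.
    ``eta``: learning rate.
    ``c_reg``: firing-rate regularization coefficient (0 disables it);
    ``f_target`` is the target rate in Hz.
    ``optimizer``: plain ``sgd`` (default), ``momentum``, or ``adam``.
    """

    mode: str = "random"
    loss_kind: str = "classification"
    eta: float = 0.01
    c_reg: float = 0.0
    f_target: float = 10.0
    optimizer: str = "sgd"
    momentum: float = 0.9
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.mode not in FEEDBACK_MODES:
            raise ConfigurationError(f"unknown feedback mode {self.mode!r}")
        if self.optimizer not in ("sgd", "momentum", "adam"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class GradientAccumulator:
    """Additive store of proposed weight updates over steps and trials."""

    dw_in: np.ndarray
    dw_rec: np.ndarray
    dw_out: np.ndarray
    db_out: np.ndarray
    d_b_mat: np.ndarray

    @classmethod
    def zeros(cls, config: NetworkConfig, dtype=np.float64) -> "GradientAccumulator":
        return cls(
            dw_in=np.zeros((config.n_rec, config.n_in), dtype=dtype),
            dw_rec=np.zeros((config.n_rec, config.n_rec), dtype=dtype),
            dw_out=np.zeros((config.n_out, config.n_rec), dtype=dtype),
            db_out=np.zeros(config.n_out, dtype=dtype),
            d_b_mat=np.zeros((config.n_rec, config.n_out), dtype=dtype),
        )

    def reset(self) -> None:
        for arr in (self.dw_in, self.dw_rec, self.dw_out, self.db_out, self.d_b_mat):
            arr[...] = 0.0


def make_broadcast(mode: str, w_out: np.ndarray,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Construct the feedback matrix for the given mode.

    Symmetric feedback is the transpose of the output weights; random and
    adaptive feedback is drawn Gaussian with matching statistics (frozen
    afterwards in random mode, plastic in adaptive mode).
    """
    w_out = np.asarray(w_out)
    if mode == "symmetric":
        return w_out.T.copy()
    if mode in ("random", "adaptive"):
        if rng is None:
            raise ConfigurationError(f"{mode} feedback requires a random generator")
        n_out, n_rec = w_out.shape
        return rng.normal(0.0, 1.0 / np.sqrt(n_rec), size=(n_rec, n_out))
    raise ConfigurationError(f"unknown feedback mode {mode!r}")


def regression_learning_signal(y: np.ndarray, y_star: np.ndarray,
                               b_mat: np.ndarray) -> np.ndarray:
    """Per-neuron learning signal ``L_j = sum_k B_jk (y_k - y*_k)``."""
    return (np.asarray(y) - np.asarray(y_star)) @ b_mat.T


def classification_learning_signal(y: np.ndarray, pi_star: np.ndarray,
                                   b_mat: np.ndarray) -> np.ndarray:
    """Per-neuron signal from the softmax error ``pi - pi*``.

    Rows of ``pi_star`` that are identically zero (masked steps) contribute
    nothing, because they are expected to be zeroed by the loss mask
    upstream; here the signal is computed for the given error as-is.
    """
    return (softmax(np.asarray(y)) - np.asarray(pi_star)) @ b_mat.T


def accumulate_recurrent_updates(acc: GradientAccumulator, L: np.ndarray,
                                 e_bar_rec: np.ndarray,
                                 e_bar_in: np.ndarray | None = None,
                                 eta: float = 1.0) -> GradientAccumulator:
    """Add one step's three-factor update ``-eta * L_j * ebar_ji``.

    ``L`` has shape ``(..., n_rec)`` and the filtered traces
    ``(..., n_rec, n_pre)``; leading axes (batch) are summed over.
    """
    upd = -eta * (L[..., :, None] * e_bar_rec)
    acc.dw_rec += upd.reshape(-1, *upd.shape[-2:]).sum(axis=0)
    np.fill_diagonal(acc.dw_rec, 0.0)
    if e_bar_in is not None:
        upd_in = -eta * (L[..., :, None] * e_bar_in)
        acc.dw_in += upd_in.reshape(-1, *upd_in.shape[-2:]).sum(axis=0)
    return acc


def output_layer_updates(acc: GradientAccumulator, err: np.ndarray,
                         z_bar: np.ndarray, eta: float = 1.0,
                         bias_kernel: float = 1.0) -> GradientAccumulator:
    """Exact-gradient readout update from one step's masked output error.

    ``err`` is ``y - y*`` (regression) or ``pi - pi*`` (classification),
    already masked; ``z_bar`` is the kappa-filtered spike train.
    ``bias_kernel`` is the kappa-filtered unit drive ``F_kappa(1)`` through
    which the bias enters the leaky readout (1 when kappa = 0); with it the
    update is the exact readout gradient.
    """
    err = np.atleast_2d(err)
    z_bar = np.atleast_2d(z_bar)
    acc.dw_out += -eta * err.T @ z_bar
    acc.db_out += -eta * bias_kernel * err.sum(axis=0)
    return acc


def adaptive_broadcast_update(acc: GradientAccumulator, err: np.ndarray,
                              z_bar: np.ndarray, mode: str,
                              eta: float = 1.0) -> GradientAccumulator:
    """Mirror the readout update onto the feedback weights (adaptive mode)."""
    if mode != "adaptive":
        raise ConfigurationError("broadcast plasticity only applies in adaptive mode")
    err = np.atleast_2d(err)
    z_bar = np.atleast_2d(z_bar)
    acc.d_b_mat += (-eta * err.T @ z_bar).T
    return acc


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Optimizer:
    """Applies accumulated gradients to the weights.

    ``sgd`` performs ``w += -eta * g``; ``momentum`` keeps a velocity;
    ``adam`` keeps first/second moment estimates per weight block.
    """

    def __init__(self, learn: LearningMode):
        self.learn = learn
        self._state: dict[str, list[np.ndarray]] = {}
        self._t = 0

    def apply(self, weights: SynapticWeights, grads: dict[str, np.ndarray]) -> None:
        lm = self.learn
        self._t += 1
        for name, g in grads.items():
            w = getattr(weights, name)
            if lm.optimizer == "sgd":
                w -= lm.eta * g
            elif lm.optimizer == "momentum":
                vel = self._state.setdefault(name, [np.zeros_like(w)])[0]
                vel *= lm.momentum
                vel += g
                w -= lm.eta * vel
            else:  # adam
                m, v = self._state.setdefault(
                    name, [np.zeros_like(w), np.zeros_like(w)])
                m *= lm.adam_beta1
                m += (1 - lm.adam_beta1) * g
                v *= lm.adam_beta2
                v += (1 - lm.adam_beta2) * g * g
                mhat = m / (1 - lm.adam_beta1 ** self._t)
                vhat = v / (1 - lm.adam_beta2 ** self._t)
                w -= lm.eta * mhat / (np.sqrt(vhat) + lm.adam_eps)
        np.fill_diagonal(weights.w_rec, 0.0)


# ---------------------------------------------------------------------------
# Fused batched forward + eligibility + accumulation pass
# ---------------------------------------------------------------------------

def _forward_learn_batch(weights: SynapticWeights, config: NetworkConfig,
                         x: np.ndarray, target: np.ndarray,
                         loss_mask: np.ndarray, learn: LearningMode,
                         b_mat: np.ndarray, compute_grads: bool = True,
                         dtype=np.float32):
    """One batch: simulate, maintain eligibility traces online, accumulate
    gradients.  Returns (grads or None, metrics dict)."""
    B, T, n_in = x.shape
    n_rec, n_out = config.n_rec, config.n_out
    alpha = dtype(config.alpha)
    rho = dtype(config.rho)
    kappa = dtype(config.kappa)
    v_th = dtype(config.v_th)
    beta_row = config.beta_vector(dtype=dtype)
    beta_col = beta_row[:, None]
    adaptive = np.zeros(n_rec, dtype=dtype)
    adaptive[config.n_regular:] = 1
    gamma_over_vth = dtype(config.gamma_pd / config.v_th)
    inv_vth = dtype(1.0 / config.v_th)

    w_in = weights.w_in.astype(dtype)
    w_rec = weights.w_rec.astype(dtype)
    w_out = weights.w_out.astype(dtype)
    b_out = weights.b_out.astype(dtype)
    b_mat_c = b_mat.astype(dtype)

    xd = np.ascontiguousarray(x, dtype=dtype)
    target = np.asarray(target, dtype=dtype)
    mask = np.asarray(loss_mask, dtype=dtype)

    v = np.zeros((B, n_rec), dtype=dtype)
    a = np.zeros_like(v)
    z = np.zeros_like(v)
    r = np.zeros((B, n_rec), dtype=np.int32)
    y = np.zeros((B, n_out), dtype=dtype)
    z_hist = np.zeros((T, B, n_rec), dtype=dtype)

    # presynaptic axis: recurrent spikes and input spikes concatenated
    n_pre = n_rec + n_in
    ad = slice(config.n_regular, n_rec)  # adaptive rows
    if compute_grads:
        pre = np.zeros((B, n_pre), dtype=dtype)
        eps_v = np.zeros((B, n_pre), dtype=dtype)
        eps_v_prev = np.zeros_like(eps_v)
        eps_a = np.zeros((B, n_rec - config.n_regular, n_pre), dtype=dtype)
        ebar = np.zeros((B, n_rec, n_pre), dtype=dtype)
        esum = np.zeros_like(ebar) if learn.c_reg else None
        psi_prev = np.zeros((B, n_rec), dtype=dtype)
        zbar_out = np.zeros((B, n_rec), dtype=dtype)
        bias_kern = 0.0
        g_pre = np.zeros((n_rec, n_pre), dtype=np.float64)
        g_out = np.zeros((n_out, n_rec), dtype=np.float64)
        g_b = np.zeros(n_out, dtype=np.float64)
        beta_ad = beta_col[ad]

    total_loss = 0.0
    spike_count = np.zeros(n_rec, dtype=np.float64)
    pi_sum = np.zeros((B, n_out), dtype=np.float64)

    zero_z = np.zeros((B, n_rec), dtype=dtype)
    d = config.delay
    for t in range(T):
        z_pre = z_hist[t - d] if t >= d else zero_z
        v = alpha * v + z_pre @ w_rec.T + xd[:, t] @ w_in.T - z * v_th
        a = (rho * a + z) * adaptive
        A = v_th + beta_col.T * a
        refr = r > 0
        fired = (v >= A) & ~refr
        z = fired.astype(dtype)
        psi = gamma_over_vth * np.maximum(
            dtype(0.0), dtype(1.0) - np.abs((v - A) * inv_vth))
        psi[refr] = 0
        r = np.where(fired, config.n_refractory, np.maximum(r - 1, 0))
        z_hist[t] = z
        y = kappa * y + z @ w_out.T + b_out

        m_t = mask[:, t]
        if learn.loss_kind == "regression":
            err = (y - target[:, t]) * m_t[:, None]
            total_loss += 0.5 * float((err * (y - target[:, t])).sum())
        else:
            pi = softmax(y)
            err = (pi - target[:, t]) * m_t[:, None]
            logp = np.log(np.clip(pi, 1e-30, None))
            total_loss += -float((m_t[:, None] * target[:, t] * logp).sum())
            pi_sum += (m_t[:, None] * pi).astype(np.float64)
        spike_count += z.sum(axis=0).astype(np.float64)

        if not compute_grads:
            continue

        # eligibility traces over the concatenated presynaptic axis
        pre[:, :n_rec] = z_pre
        pre[:, n_rec:] = xd[:, t]
        eps_v = alpha * eps_v + pre
        psi_c = psi_prev[:, ad, None]
        eps_a *= (rho - psi_c * beta_ad)
        eps_a += psi_c * eps_v_prev[:, None, :]
        # trace: psi * eps_v for all rows, minus beta * eps_a for ALIF rows
        e = psi[:, :, None] * eps_v[:, None, :]
        e[:, ad, :] -= (psi[:, ad, None] * beta_ad) * eps_a
        ebar *= kappa
        ebar += e
        if esum is not None:
            esum += e
        psi_prev = psi
        eps_v_prev = eps_v

        L = err @ b_mat_c.T  # (B, n_rec)
        g_pre += np.einsum("bj,bji->ji", L, ebar, optimize=True)
        zbar_out = kappa * zbar_out + z
        bias_kern = float(kappa) * bias_kern + 1.0
        g_out += err.T @ zbar_out
        g_b += bias_kern * err.sum(axis=0).astype(np.float64)

    dt_sec = config.dt / 1000.0
    rates = spike_count / (B * T * dt_sec)  # Hz per neuron
    metrics = {
        "loss": total_loss / B,
        "mean_rate": float(rates.mean()),
    }
    if learn.loss_kind == "classification":
        pred = pi_sum.argmax(axis=1)
        true = np.asarray(target).max(axis=1).argmax(axis=1)
        metrics["accuracy"] = float((pred == true).mean())

    if not compute_grads:
        return None, metrics

    g_pre = g_pre / B
    if learn.c_reg:
        # exact gradient of c_reg/2 * sum_j (f_j - f_target)^2, rates over
        # the whole batch, through the unfiltered trace sum
        l_reg = learn.c_reg * (rates - learn.f_target) / (B * T * dt_sec)
        g_pre = g_pre + l_reg[:, None] * esum.sum(axis=0)
    grads = {"w_in": g_pre[:, n_rec:].copy(),
             "w_rec": g_pre[:, :n_rec].copy(),
             "w_out": g_out / B, "b_out": g_b / B}
    np.fill_diagonal(grads["w_rec"], 0.0)
    return grads, metrics


def evaluate(weights: SynapticWeights, config: NetworkConfig,
             x: np.ndarray, target: np.ndarray, loss_mask: np.ndarray,
             learn: LearningMode) -> dict:
    """Forward-only metrics (loss, accuracy, firing rate) on a batch."""
    _, metrics = _forward_learn_batch(
        weights, config, np.asarray(x), target, loss_mask, learn,
        b_mat=weights.b_mat, compute_grads=False)
    return metrics


def train_supervised(task, config: NetworkConfig, learn: LearningMode,
                     weights: SynapticWeights | None = None,
                     n_iterations: int = 100, batch_size: int = 64,
                     seed: int = 0, eval_every: int = 10,
                     heldout_size: int = 128, weight_gain: float = 1.0,
                     dtype=np.float32, polyak_from: int | None = None,
                     verbose: bool = False):
    """Batched supervised training with the three-factor rule.

    ``task`` must provide ``sample_batch(rng, n) -> (x, target, loss_mask)``
    (a labelled trial batch).  Updates are accumulated over each batch and
    applied once per batch.  Returns ``(weights, history)`` where history
    is a list of per-iteration records; evaluation records on a fixed
    held-out batch are interleaved every ``eval_every`` iterations.

    If ``polyak_from`` is given, the returned weights are the running
    average of the iterates from that iteration onward (tail averaging),
    which removes the batch-to-batch fluctuation of the final model.
    """
    from .seeding import substream

    rng_w = substream(seed, "weights")
    rng_task = substream(seed, "task")
    rng_held = substream(seed, "heldout")

    if weights is None:
        from .dynamics import initialize_weights
        weights = initialize_weights(config, rng_w, feedback=learn.mode,
                                     gain=weight_gain)
    if learn.mode == "symmetric":
        weights.b_mat = weights.w_out.T.copy()
    b_frozen = weights.b_mat.copy()

    held = task.sample_batch(rng_held, heldout_size)
    optimizer = Optimizer(learn)
    history = []
    avg: dict[str, np.ndarray] | None = None
    n_avg = 0
    for it in range(n_iterations):
        x, target, loss_mask = task.sample_batch(rng_task, batch_size)
        b_mat = weights.w_out.T if learn.mode == "symmetric" else weights.b_mat
        grads, metrics = _forward_learn_batch(
            weights, config, x, target, loss_mask, learn, b_mat, dtype=dtype)
        if not np.isfinite(metrics["loss"]):
            raise RuntimeError(
                f"training diverged at iteration {it}: loss={metrics['loss']}")
        if learn.mode == "adaptive":
            grads["b_mat"] = grads["w_out"].T.copy()
        if learn.mode == "random":
            weights.b_mat = b_frozen  # guaranteed fixed
        optimizer.apply(weights, grads)
        if polyak_from is not None and it >= polyak_from:
            if avg is None:
                avg = {k: getattr(weights, k).copy()
                       for k in ("w_in", "w_rec", "w_out", "b_out", "b_mat")}
            else:
                n = n_avg
                for k, acc_w in avg.items():
                    acc_w += (getattr(weights, k) - acc_w) / (n + 1)
            n_avg += 1
        rec = {"iteration": it, **metrics}
        if eval_every and (it % eval_every == 0 or it == n_iterations - 1):
            ev = evaluate(weights, config, *held, learn)
            rec.update({f"heldout_{k}": v for k, v in ev.items()})
            if verbose:
                print(f"[{it:4d}] " + " ".join(f"{k}={v:.4f}" for k, v in rec.items()
                                               if k != "iteration"))
        history.append(rec)
    if avg is not None:
        for k, acc_w in avg.items():
            getattr(weights, k)[...] = acc_w
        np.fill_diagonal(weights.w_rec, 0.0)
        if learn.mode == "symmetric":
            weights.b_mat = weights.w_out.T.copy()
    return weights, history
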