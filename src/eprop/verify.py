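"""Randomized verification suite for the gradient identities.

Draws small random networks (mixed LIF/ALIF, both loss kinds), runs them
on random spike inputs, and measures

* the deviation between the trace-based gradient with ideal learning
  signals and the backward-pass gradient (the re-factorization identity),
* the deviation between the recursive eligibility traces and their
  brute-force definition,
* the deviation of the full symmetric online update from the exact
  gradient when the recurrent weights are zero (feedforward exactness).

Used by the ``check-gradients`` CLI subcommand and by the test suite.
"""

from __future__ import annotations

import numpy as np

from .config import NetworkConfig
from .dynamics import SynapticWeights, TrialRecording, initialize_weights, run_trial
from .eligibility import brute_force_eligibility, eligibility_history
from .learning import (GradientAccumulator, LearningMode,
                       accumulate_recurrent_updates, output_layer_updates)
from .losses import output_error
from .oracle import backward_pass, eprop_gradient_with_ideal_signal

__all__ = ["random_instance", "gradient_identity_deviation",
           "recursion_vs_definition_deviation", "feedforward_deviation",
           "run_suite"]

_BLOCKS = ("dw_in", "dw_rec", "dw_out", "db_out")


def random_instance(rng: np.random.Generator, n_adaptive: int | None = None,
                    T: int | None = None, recurrent: bool = True):
    """One small random network + trial: (config, weights, x, targets, mask)."""
    n_in = int(rng.integers(2, 5))
    n_rec = int(rng.integers(4, 9))
    n_out = int(rng.integers(1, 4))
    if n_adaptive is None:
        n_adaptive = int(rng.integers(0, n_rec + 1))
    if T is None:
        T = int(rng.integers(10, 26))
    config = NetworkConfig(
        n_in=n_in, n_rec=n_rec, n_out=n_out, n_adaptive=n_adaptive,
        tau_m=float(rng.uniform(10, 30)), tau_a=float(rng.uniform(50, 500)),
        tau_out=float(rng.uniform(3, 30)), v_th=0.5, beta=0.07,
        n_refractory=int(rng.integers(0, 3)))
    weights = initialize_weights(config, rng, feedback="symmetric", gain=1.0)
    if not recurrent:
        weights.w_rec[...] = 0.0
    x = (rng.random((T, n_in)) < 0.3).astype(np.int8)
    y_reg = rng.normal(0.0, 0.5, size=(T, n_out))
    cls = rng.integers(n_out)
    pi_star = np.zeros((T, n_out))
    pi_star[:, cls] = 1.0
    mask = (rng.random(T) < 0.8).astype(float)
    return config, weights, x, {"regression": y_reg, "classification": pi_star}, mask


def _block_deviation(g_a, g_b) -> float:
    worst = 0.0
    for name in _BLOCKS:
        a = np.asarray(getattr(g_a, name), dtype=float)
        b = np.asarray(getattr(g_b, name), dtype=float)
        scale = max(np.abs(a).max(), np.abs(b).max(), 1e-12)
        worst = max(worst, float(np.abs(a - b).max() / scale))
    return worst


def gradient_identity_deviation(seed: int, n_networks: int = 20,
                                n_adaptive: int | None = None) -> float:
    """Max relative deviation, over random networks and both losses, of the
    ideal-signal trace gradient from the backward-pass gradient.

    ``n_adaptive=0`` restricts the sweep to pure LIF networks; the default
    draws a random mix of LIF and ALIF rows per network.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_networks):
        config, weights, x, targets, mask = random_instance(rng, n_adaptive=n_adaptive)
        rec = run_trial(weights, x, config, loss_mask=mask)
        for kind, target in targets.items():
            exact = backward_pass(rec, weights, config, target, kind)
            via_traces = eprop_gradient_with_ideal_signal(
                rec, weights, config, target, kind)
            worst = max(worst, _block_deviation(exact, via_traces))
    return worst


def recursion_vs_definition_deviation(seed: int, n_networks: int = 6) -> float:
    """Max absolute deviation of the recursive eligibility traces from the
    explicit sum-of-products definition, over every synapse and step."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_networks):
        config, weights, x, _targets, mask = random_instance(rng, T=20)
        rec = run_trial(weights, x, config, loss_mask=mask)
        for source in ("rec", "in"):
            _, _, e, _ = eligibility_history(rec, config, source=source)
            n_pre = e.shape[-1]
            for t in range(rec.n_steps):
                for j in range(config.n_rec):
                    for i in range(n_pre):
                        ref = brute_force_eligibility(rec, config, j, i, t,
                                                      source=source)
                        worst = max(worst, abs(e[t, j, i] - ref))
    return worst


def feedforward_deviation(seed: int, n_networks: int = 10) -> float:
    """With zero recurrent weights, the full symmetric online update must
    equal the exact gradient; returns the max relative deviation."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_networks):
        config, weights, x, targets, mask = random_instance(rng, recurrent=False)
        rec = run_trial(weights, x, config, loss_mask=mask)
        for kind, target in targets.items():
            exact = backward_pass(rec, weights, config, target, kind)
            # symmetric online update with eta = 1 (sign flipped to gradients)
            err = output_error(rec.y, target, rec.loss_mask, kind)
            L = err @ weights.w_out  # symmetric feedback: B = w_out.T
            _, _, _, ebar_rec = eligibility_history(rec, config, source="rec")
            _, _, _, ebar_in = eligibility_history(rec, config, source="in")
            acc = GradientAccumulator.zeros(config)
            for t in range(rec.n_steps):
                accumulate_recurrent_updates(acc, L[t], ebar_rec[t], ebar_in[t])
            z_bar = np.zeros(config.n_rec)
            kern = 0.0
            for t in range(rec.n_steps):
                z_bar = config.kappa * z_bar + rec.z[t]
                kern = config.kappa * kern + 1.0
                output_layer_updates(acc, err[t], z_bar, bias_kernel=kern)
            online = type(exact)(dE_dz=exact.dE_dz, dw_in=-acc.dw_in,
                                 dw_rec=-acc.dw_rec, dw_out=-acc.dw_out,
                                 db_out=-acc.db_out)
            worst = max(worst, _block_deviation(exact, online))
    return worst


def run_suite(seed: int = 1) -> dict[str, float]:
    """Run all three checks; returns the named max deviations."""
    return {
        "gradient_identity_max_rel_dev": gradient_identity_deviation(seed),
        "eligibility_recursion_max_abs_dev": recursion_vs_definition_deviation(seed),
        "feedforward_exactness_max_rel_dev": feedforward_deviation(seed),
    }
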