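"""Loss functions on readout trajectories: squared error and cross-entropy.

Both losses are sums over time steps, weighted by the per-step loss mask.
Their derivative with respect to the readout value at a step is the masked
output error: ``y - y*`` for regression, ``softmax(y) - pi*`` for
classification.
"""

from __future__ import annotations

import numpy as np

LOSS_KINDS = ("regression", "classification")


def softmax(y: np.ndarray, axis: int = -1) -> np.ndarray:
    shifted = y - y.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def output_error(y: np.ndarray, target: np.ndarray, loss_mask: np.ndarray,
                 loss_kind: str) -> np.ndarray:
    """Masked per-step derivative of the loss w.r.t. the readouts.

    ``y`` and ``target`` have shape ``(..., T, n_out)``; ``loss_mask``
    broadcasts over the readout axis.
    """
    if loss_kind == "regression":
        err = y - target
    elif loss_kind == "classification":
        err = softmax(y) - target
    else:
        raise ValueError(f"unknown loss kind {loss_kind!r}; expected one of {LOSS_KINDS}")
    return err * np.asarray(loss_mask)[..., None]


def loss_value(y: np.ndarray, target: np.ndarray, loss_mask: np.ndarray,
               loss_kind: str) -> float:
    """Scalar loss of a trial or batch (sum over steps and readouts)."""
    m = np.asarray(loss_mask)[..., None]
    if loss_kind == "regression":
        return float(0.5 * (m * (y - target) ** 2).sum())
    if loss_kind == "classification":
        logp = np.log(np.clip(softmax(y), 1e-30, None))
        return float(-(m * target * logp).sum())
    raise ValueError(f"unknown loss kind {loss_kind!r}; expected one of {LOSS_KINDS}")
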