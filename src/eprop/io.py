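"""Plain-text and named-array serialization helpers.

Spike trains travel either as dense binary arrays or as columnar event
lists (``time_step<TAB>neuron_id``, 0-based, half-open window ``[0, T)``).
Learning curves are written as headed CSV; weight and recording snapshots
go into single-file named-array containers (``.npz``).
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .dynamics import SynapticWeights

__all__ = ["events_to_dense", "dense_to_events", "read_events", "write_events",
           "write_curve", "save_weights", "load_weights"]


def events_to_dense(events: np.ndarray, n_steps: int, n_channels: int) -> np.ndarray:
    """Convert an event list ``(time_step, neuron_id)`` to a dense binary
    raster of shape ``(n_steps, n_channels)``."""
    events = np.atleast_2d(np.asarray(events, dtype=np.int64))
    x = np.zeros((n_steps, n_channels), dtype=np.int8)
    if events.size == 0:
        return x
    t, i = events[:, 0], events[:, 1]
    if (t < 0).any() or (t >= n_steps).any():
        raise ValueError("event time outside the trial window [0, T)")
    if (i < 0).any() or (i >= n_channels).any():
        raise ValueError("event neuron id outside [0, n_channels)")
    x[t, i] = 1
    return x


def dense_to_events(x: np.ndarray) -> np.ndarray:
    """Convert a dense binary raster to a sorted event list."""
    t, i = np.nonzero(np.asarray(x))
    return np.column_stack([t, i]).astype(np.int64)


def read_events(path) -> np.ndarray:
    """Read a tab/whitespace-separated event list with an optional header."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if not parts[0].lstrip("-").isdigit():
                continue  # header row
            rows.append((int(parts[0]), int(parts[1])))
    return np.array(rows, dtype=np.int64).reshape(-1, 2)


def write_events(path, events: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("time_step\tneuron_id\n")
        for t, i in np.asarray(events, dtype=np.int64):
            fh.write(f"{t}\t{i}\n")


def write_curve(path, history: list[dict]) -> None:
    """Write a learning-curve log as headed CSV (one row per record)."""
    if not history:
        Path(path).write_text("")
        return
    keys = sorted({k for rec in history for k in rec},
                  key=lambda k: (k != "iteration", k != "batch", k))
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(history)


def save_weights(path, weights: SynapticWeights) -> None:
    np.savez(path, w_in=weights.w_in, w_rec=weights.w_rec,
             w_out=weights.w_out, b_out=weights.b_out, b_mat=weights.b_mat)


def load_weights(path) -> SynapticWeights:
    with np.load(path) as data:
        return SynapticWeights(data["w_in"], data["w_rec"], data["w_out"],
                               data["b_out"], data["b_mat"])
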