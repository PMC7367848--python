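"""Canonical desk-scale experiments, shared by the CLI, the test suite,
and the acceptance script.

These fix the study conditions — network sizes, task preset, learning
hyperparameters, training length — so every entry point runs the same
experiment and differs only in the seed.
"""

from __future__ import annotations

import numpy as np

from .config import NetworkConfig
from .learning import LearningMode, evaluate, train_supervised
from .rl import RLConfig, run_episode_batch, train_actor_critic
from .seeding import substream
from .tasks import CatchEnv, CueAccumulationParams, CueAccumulationTask

__all__ = ["train_cue_accumulation_reduced", "train_catch", "evaluate_catch"]


def train_cue_accumulation_reduced(seed: int, n_adaptive: int = 50,
                                   n_iterations: int = 300,
                                   n_fine_iterations: int = 150,
                                   heldout_size: int = 512,
                                   verbose: bool = False):
    """Random e-prop on the reduced-scale cue-accumulation task.

    100 recurrent neurons (``n_adaptive`` of them with threshold
    adaptation, 50 by default; 0 gives the all-LIF control with otherwise
    matched parameters).  Two Adam phases (5e-3 then 1e-3) over batches
    of 32.  Returns ``(heldout_metrics, weights, history)`` with the
    held-out metrics measured on a fresh batch of trials.
    """
    task = CueAccumulationTask(CueAccumulationParams.reduced())
    config = NetworkConfig(n_in=task.n_in, n_rec=100, n_out=2,
                           n_adaptive=n_adaptive, tau_a=400.0, v_th=0.6,
                           seed=seed)
    coarse = LearningMode(mode="random", loss_kind="classification", eta=5e-3,
                          c_reg=1e-4, f_target=10.0, optimizer="adam")
    fine = LearningMode(mode="random", loss_kind="classification", eta=1e-3,
                        c_reg=1e-4, f_target=10.0, optimizer="adam")
    weights, hist1 = train_supervised(
        task, config, coarse, n_iterations=n_iterations, batch_size=32,
        seed=seed, eval_every=50 if verbose else 0, verbose=verbose)
    weights, hist2 = train_supervised(
        task, config, fine, weights=weights, n_iterations=n_fine_iterations,
        batch_size=32, seed=seed + 1000, eval_every=0,
        polyak_from=n_fine_iterations // 3, verbose=verbose)
    x, target, mask = task.sample_batch(substream(seed, "final-eval"),
                                        heldout_size)
    metrics = evaluate(weights, config, x, target, mask, fine)
    return metrics, weights, hist1 + hist2


_CATCH_STEPS_PER_CELL = 3


def _catch_config(seed: int) -> tuple[NetworkConfig, RLConfig]:
    env0 = CatchEnv(steps_per_cell=_CATCH_STEPS_PER_CELL)
    config = NetworkConfig(n_in=env0.n_obs, n_rec=64, n_out=4, n_adaptive=16,
                           tau_a=100.0, v_th=0.6, seed=seed)
    rl = RLConfig(n_actions=3, gamma=0.98, c_v=0.5, eta=3e-3)
    return config, rl


def train_catch(seed: int, n_batches: int = 700, eta: float | None = None,
                verbose: bool = False):
    """Actor-critic training on the catch grid (64-neuron LSNN).

    Returns ``(weights, config, rl, history)``; pass ``eta=0`` for the
    no-learning control.
    """
    config, rl = _catch_config(seed)
    if eta is not None:
        rl.eta = eta
    weights, history = train_actor_critic(
        lambda s: CatchEnv(steps_per_cell=_CATCH_STEPS_PER_CELL, seed=s),
        config, rl, n_batches=n_batches, batch_size=32, seed=seed,
        weight_gain=0.6, verbose=verbose)
    return weights, config, rl, history


def evaluate_catch(weights, config, rl, seed: int, n_episodes: int = 500):
    """Frozen-policy evaluation; returns (mean return, standard error)."""
    rng = np.random.default_rng(seed)
    returns = []
    B = 50
    for rep in range(n_episodes // B):
        envs = [CatchEnv(steps_per_cell=_CATCH_STEPS_PER_CELL,
                         seed=int(rng.integers(2 ** 31))) for _ in range(B)]
        _, stats = run_episode_batch(envs, weights, config, rl, rng, learn=False)
        returns.extend(stats["returns"])
    returns = np.asarray(returns)
    return float(returns.mean()), float(returns.std() / np.sqrt(len(returns)))
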