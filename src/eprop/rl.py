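"""Reward-based learning: actor-critic policy gradient with eligibility traces.

The recurrent network drives two readout heads: K policy readouts whose
softmax defines a stochastic policy, and one value readout estimating the
expected discounted return.  Temporal-difference errors
``delta = r + gamma*V' - V`` act as a global third factor: the synaptic
update is ``-eta * delta_t * F_gamma(L_t * ebar)``, where the per-neuron
learning signal ``L`` combines the broadcast policy error
``pi - onehot(action)`` (zero off decision steps) with a constant value
feedback ``-c_V * B_V``, and ``F_gamma`` is an exponential filter with the
discount factor — the extra per-synapse trace that temporal-difference
learning requires.  The two readout heads follow the mirrored updates
built from their own kappa-filtered spike trains.

Training is strictly online, single-agent: no replay, no parallel
actors.  Stability over long horizons is addressed by a schedule of
increasing episode lengths with learning rates inversely proportional to
the length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, NetworkConfig
from .dynamics import SynapticWeights, initialize_weights
from .losses import softmax

__all__ = [
    "RLConfig", "policy_probs", "td_error", "rl_learning_signal",
    "rl_weight_update", "episode_schedule", "run_episode_batch",
    "train_actor_critic",
]


@dataclass
class RLConfig:
    """Actor-critic hyperparameters.

    ``gamma``: per-simulation-step reward discount; ``c_v``: weight of the
    critic loss in the combined objective; ``eta``: base learning rate;
    ``feedback``: how the head feedback weights ``B_pi``/``B_V`` are set
    (symmetric = transposed head weights, or fixed random).
    """

    n_actions: int = 3
    gamma: float = 0.99
    c_v: float = 0.5
    eta: float = 3e-3
    feedback: str = "symmetric"

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigurationError(f"gamma={self.gamma} outside [0, 1]")
        if self.feedback not in ("symmetric", "random"):
            raise ConfigurationError(f"unknown feedback mode {self.feedback!r}")


def policy_probs(y_policy: np.ndarray) -> np.ndarray:
    """Action probabilities: softmax over the policy readouts."""
    return softmax(np.asarray(y_policy, dtype=float))


def td_error(r, v_t, v_next, gamma: float):
    """Temporal-difference error ``delta = r + gamma*V_next - V_t``.

    Pass ``v_next = 0`` at terminal steps.
    """
    return np.asarray(r) + gamma * np.asarray(v_next) - np.asarray(v_t)


def rl_learning_signal(pi: np.ndarray, action_onehot: np.ndarray,
                       b_pi: np.ndarray, b_v: np.ndarray, c_v: float,
                       is_decision_step) -> np.ndarray:
    """Per-neuron learning signal of the actor-critic rule.

    ``L_j = -c_v * B_j^V + sum_k B_jk^pi (pi_k - onehot_k)``; the policy
    term is defined to vanish at steps where no action is committed.
    """
    pol_err = np.asarray(pi) - np.asarray(action_onehot)
    dec = np.asarray(is_decision_step, dtype=float)
    pol = (pol_err * dec[..., None]) @ b_pi.T
    return pol - c_v * np.asarray(b_v)


def rl_weight_update(acc: np.ndarray, delta, f_gamma_acc: np.ndarray,
                     eta: float) -> np.ndarray:
    """Accumulate one step: ``acc += -eta * delta * F_gamma(L*ebar)``.

    ``f_gamma_acc`` is the discount-filtered product of learning signal
    and filtered eligibility trace, maintained by the caller; ``delta``
    broadcasts over trailing synapse axes.
    """
    acc += -eta * np.asarray(delta)[..., None, None] * f_gamma_acc
    return acc


def episode_schedule(phase_lengths, base_eta: float):
    """Stabilizing schedule: longer episodes get proportionally smaller
    learning rates, so that ``length * eta`` is constant across phases."""
    lengths = list(phase_lengths)
    if not lengths:
        raise ConfigurationError("schedule needs at least one phase")
    if any(b <= a for a, b in zip(lengths, lengths[1:])):
        raise ConfigurationError("episode lengths must be strictly increasing")
    return [(length, base_eta * lengths[0] / length) for length in lengths]


# ---------------------------------------------------------------------------
# Batched episode runner
# ---------------------------------------------------------------------------

def run_episode_batch(envs, weights: SynapticWeights, config: NetworkConfig,
                      rl: RLConfig, rng: np.random.Generator,
                      learn: bool = True, eta: float | None = None,
                      b_pi: np.ndarray | None = None,
                      b_v: np.ndarray | None = None):
    """Play one episode per environment in lockstep, accumulating updates.

    All environments must yield episodes of the same length.  Each
    environment step is presented for ``steps_per_cell`` simulation steps;
    the action is committed on the last of them.  Returns
    ``(grads or None, stats)``; stats holds per-episode returns, the mean
    squared TD error, and the mean firing rate.
    """
    if config.delay != 1:
        raise ConfigurationError("the episodic runner assumes a 1-step delay")
    B = len(envs)
    K = rl.n_actions
    pol_sl = slice(0, K)
    val_row = K
    if config.n_out != K + 1:
        raise ConfigurationError("n_out must equal n_actions + 1 (policy + value)")
    n_rec, n_in = config.n_rec, config.n_in
    alpha, rho, kappa = config.alpha, config.rho, config.kappa
    v_th = config.v_th
    gamma = rl.gamma
    eta = rl.eta if eta is None else eta
    beta_row = config.beta_vector()
    beta_col = beta_row[:, None]
    adaptive = np.zeros(n_rec)
    adaptive[config.n_regular:] = 1
    spc = getattr(envs[0], "steps_per_cell", 1)

    if b_pi is None:
        b_pi = weights.w_out[pol_sl].T
    if b_v is None:
        b_v = weights.w_out[val_row]

    obs = np.stack([env.reset() for env in envs]).astype(float)
    n_env_steps = envs[0].episode_length

    v = np.zeros((B, n_rec))
    a = np.zeros_like(v)
    z = np.zeros_like(v)
    r_cnt = np.zeros((B, n_rec), dtype=np.int64)
    y = np.zeros((B, config.n_out))

    if learn:
        eps_v_rec = np.zeros((B, n_rec))
        eps_v_in = np.zeros((B, n_in))
        eps_v_rec_prev = np.zeros_like(eps_v_rec)
        eps_v_in_prev = np.zeros_like(eps_v_in)
        psi_prev = np.zeros((B, n_rec))
        eps_a_rec = np.zeros((B, n_rec, n_rec))
        eps_a_in = np.zeros((B, n_rec, n_in))
        ebar_rec = np.zeros_like(eps_a_rec)
        ebar_in = np.zeros_like(eps_a_in)
        fg_rec = np.zeros_like(eps_a_rec)    # F_gamma(L * ebar)
        fg_in = np.zeros_like(eps_a_in)
        zbar = np.zeros((B, n_rec))          # F_kappa(z) for the heads
        kern = 0.0                           # F_kappa(1) for the biases
        fg_pol_w = np.zeros((B, K, n_rec))
        fg_pol_b = np.zeros((B, K))
        fg_val_w = np.zeros((B, n_rec))
        fg_val_b = np.zeros(B)
        g = {"w_in": np.zeros_like(weights.w_in),
             "w_rec": np.zeros_like(weights.w_rec),
             "w_out": np.zeros_like(weights.w_out),
             "b_out": np.zeros_like(weights.b_out)}

        def flush(delta):
            scale = -eta * delta
            g["w_rec"] += np.einsum("b,bji->ji", scale, fg_rec)
            g["w_in"] += np.einsum("b,bji->ji", scale, fg_in)
            g["w_out"][pol_sl] += np.einsum("b,bkj->kj", scale, fg_pol_w)
            g["b_out"][pol_sl] += scale @ fg_pol_b
            g["w_out"][val_row] += scale @ fg_val_w
            g["b_out"][val_row] += float(scale @ fg_val_b)

    returns = np.zeros(B)
    sq_td = 0.0
    n_td = 0
    spikes = 0.0
    n_sim = 0
    pending = None  # (reward, V) of the previous sim step, awaiting V_next

    eye_k = np.eye(K)
    for step in range(n_env_steps):
        for sub in range(spc):
            is_decision = sub == spc - 1
            x_t = obs  # observation driving this simulation step
            z_in = z   # previous step's spikes (1-step transmission delay)
            v = alpha * v + z_in @ weights.w_rec.T + x_t @ weights.w_in.T - z_in * v_th
            a = (rho * a + z_in) * adaptive
            A = v_th + beta_row * a
            refr = r_cnt > 0
            fired = (v >= A) & ~refr
            z = fired.astype(float)
            psi = (config.gamma_pd / v_th) * np.maximum(0.0, 1.0 - np.abs((v - A) / v_th))
            psi[refr] = 0.0
            r_cnt = np.where(fired, config.n_refractory, np.maximum(r_cnt - 1, 0))
            y = kappa * y + z @ weights.w_out.T + weights.b_out
            spikes += z.sum()
            n_sim += 1

            pi = policy_probs(y[:, pol_sl])
            V = y[:, val_row]

            if learn and pending is not None:
                # settle the previous step: its V_next is this step's V
                delta = td_error(pending[0], pending[1], V, gamma)
                sq_td += float((delta ** 2).sum())
                n_td += B
                flush(delta)

            reward = np.zeros(B)
            if is_decision:
                u = rng.random(B)
                actions = (pi.cumsum(axis=1) < u[:, None]).sum(axis=1)
                actions = np.clip(actions, 0, K - 1)
                onehot = eye_k[actions]
                new_obs = np.empty_like(obs)
                for b, env in enumerate(envs):
                    o, rwd, _done = env.step(int(actions[b]))
                    new_obs[b] = o
                    reward[b] = rwd
                returns += reward
                obs = new_obs
            else:
                onehot = np.zeros((B, K))

            if learn:
                eps_v_rec = alpha * eps_v_rec + z_in
                eps_v_in = alpha * eps_v_in + x_t
                psi_c = psi_prev[:, :, None]
                eps_a_rec = ((rho - psi_c * beta_col) * eps_a_rec
                             + psi_c * eps_v_rec_prev[:, None, :]) * adaptive[None, :, None]
                eps_a_in = ((rho - psi_c * beta_col) * eps_a_in
                            + psi_c * eps_v_in_prev[:, None, :]) * adaptive[None, :, None]
                psi_col = psi[:, :, None]
                e_rec = psi_col * (eps_v_rec[:, None, :] - beta_col * eps_a_rec)
                e_in = psi_col * (eps_v_in[:, None, :] - beta_col * eps_a_in)
                ebar_rec = kappa * ebar_rec + e_rec
                ebar_in = kappa * ebar_in + e_in
                psi_prev = psi
                eps_v_rec_prev = eps_v_rec
                eps_v_in_prev = eps_v_in

                L = rl_learning_signal(pi, onehot, b_pi, b_v, rl.c_v,
                                       np.full(B, is_decision))
                fg_rec = gamma * fg_rec + L[:, :, None] * ebar_rec
                fg_in = gamma * fg_in + L[:, :, None] * ebar_in
                zbar = kappa * zbar + z
                kern = kappa * kern + 1.0
                pol_err = (pi - onehot) if is_decision else np.zeros((B, K))
                fg_pol_w = gamma * fg_pol_w + pol_err[:, :, None] * zbar[:, None, :]
                fg_pol_b = gamma * fg_pol_b + pol_err * kern
                fg_val_w = gamma * fg_val_w + (-rl.c_v) * zbar
                fg_val_b = gamma * fg_val_b + (-rl.c_v) * kern

                pending = (reward, V)

    if learn and pending is not None:
        # terminal convention: V_next = 0
        delta = td_error(pending[0], pending[1], 0.0, gamma)
        sq_td += float((delta ** 2).sum())
        n_td += B
        flush(delta)

    stats = {
        "returns": returns,
        "mean_return": float(returns.mean()),
        "mean_sq_td": sq_td / max(n_td, 1),
        "mean_rate": float(spikes / (B * n_sim * config.dt / 1000.0) / config.n_rec),
    }
    if not learn:
        return None, stats
    for name in g:
        g[name] /= B
    np.fill_diagonal(g["w_rec"], 0.0)
    return g, stats


def train_actor_critic(env_factory, config: NetworkConfig, rl: RLConfig,
                       n_batches: int = 200, batch_size: int = 32,
                       seed: int = 0, weights: SynapticWeights | None = None,
                       weight_gain: float = 1.0, schedule=None,
                       verbose: bool = False):
    """Train the actor-critic agent over batches of parallel episodes.

    ``env_factory(seed)`` must build an independent environment instance.
    If ``schedule`` is given (a list of ``(episode_length, eta)`` pairs,
    e.g. from :func:`episode_schedule`), ``env_factory(seed, length)`` is
    called per phase and the batches are split evenly across phases.
    Returns ``(weights, history)`` with one record per batch.
    """
    from .seeding import substream

    rng_w = substream(seed, "weights")
    rng_pol = substream(seed, "policy")
    rng_env = substream(seed, "envs")

    if weights is None:
        weights = initialize_weights(config, rng_w, feedback="random",
                                     gain=weight_gain)
    if rl.feedback == "symmetric":
        b_pi_fixed = b_v_fixed = None  # resolved from w_out at every batch
    else:
        b_pi_fixed = rng_w.normal(0.0, 1.0 / np.sqrt(config.n_rec),
                                  size=(config.n_rec, rl.n_actions))
        b_v_fixed = rng_w.normal(0.0, 1.0 / np.sqrt(config.n_rec),
                                 size=config.n_rec)

    phases = schedule or [(None, rl.eta)]
    per_phase = max(1, n_batches // len(phases))
    history = []
    batch_idx = 0
    for length, eta in phases:
        if length is None:
            envs = [env_factory(int(rng_env.integers(2 ** 31)))
                    for _ in range(batch_size)]
        else:
            envs = [env_factory(int(rng_env.integers(2 ** 31)), length)
                    for _ in range(batch_size)]
        for _ in range(per_phase):
            grads, stats = run_episode_batch(
                envs, weights, config, rl, rng_pol, learn=True, eta=eta,
                b_pi=b_pi_fixed, b_v=b_v_fixed)
            if not all(np.isfinite(v).all() for v in grads.values()):
                raise RuntimeError(f"training diverged at batch {batch_idx}")
            for name, gval in grads.items():
                getattr(weights, name).__iadd__(gval)
            np.fill_diagonal(weights.w_rec, 0.0)
            rec = {"batch": batch_idx, "eta": eta,
                   **{k: v for k, v in stats.items() if k != "returns"}}
            history.append(rec)
            if verbose and batch_idx % 20 == 0:
                print(f"[{batch_idx:4d}] return={stats['mean_return']:+.3f} "
                      f"td2={stats['mean_sq_td']:.4f} rate={stats['mean_rate']:.1f}Hz")
            batch_idx += 1
    return weights, history
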