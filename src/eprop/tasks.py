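"""Synthetic task generators and the toy reinforcement-learning environment.

Three desk-scale tasks emulate the statistical structure of the
experiments the learning rule is aimed at:

* **Cue accumulation** — a delayed-decision trial: several brief cues
  arrive on a left or right input channel group early in the trial, and
  only during a short terminal recall window does the loss ask for the
  majority side.  All plasticity-relevant errors arise long after the
  evidence, which is what makes the task a temporal credit-assignment
  benchmark.
* **Pattern regression** — a frozen random spike raster must be mapped to
  a fixed sum-of-sinusoids target trace.
* **Catch** — an episodic grid environment: a ball falls one row per step
  and a paddle on the bottom row must intercept it; spike-encoded
  observations, a single +1/-1 reward at the end.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .config import ConfigurationError


# ---------------------------------------------------------------------------
# Cue accumulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CueAccumulationParams:
    """Timing and coding parameters of the cue-accumulation trial (ms).

    The default timing follows the full-scale delayed-decision protocol:
    all cues inside the first 1050 ms of a 2250 ms trial, loss mask active
    only in the last 150 ms.  ``reduced()`` returns a five-fold shorter
    preset with the same structure for quick training runs.
    """

    n_cues: int = 7
    p_left: float = 0.5
    trial_length: int = 2250
    cue_window: int = 1050
    recall_window: int = 150
    cue_duration: int = 100
    cue_gap: int = 50
    n_channels_per_side: int = 10
    n_recall_channels: int = 10
    cue_rate: float = 40.0    # Hz during an active cue / recall signal
    noise_rate: float = 1.0   # Hz background on every channel
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cues % 2 == 0 or self.n_cues <= 0:
            raise ConfigurationError("n_cues must be odd so the majority is defined")
        if self.recall_window <= 0:
            raise ConfigurationError("recall_window must be positive")
        if self.n_cues * (self.cue_duration + self.cue_gap) > self.cue_window:
            raise ConfigurationError("cues do not fit into the cue window")
        if self.cue_window + self.recall_window > self.trial_length:
            raise ConfigurationError("cue and recall windows exceed the trial length")

    @classmethod
    def reduced(cls) -> "CueAccumulationParams":
        """Desk-scale preset: same structure at one fifth of the duration.

        Cue and recall rates are scaled up five-fold so that the expected
        number of spikes per cue and per recall signal matches the
        full-scale protocol under the five-fold shorter windows.
        """
        return cls(trial_length=450, cue_window=210, recall_window=50,
                   cue_duration=20, cue_gap=10, cue_rate=200.0)

    @property
    def n_in(self) -> int:
        return 2 * self.n_channels_per_side + self.n_recall_channels

    @property
    def n_steps(self) -> int:
        return int(round(self.trial_length / self.dt))


def gen_cue_accumulation(params: CueAccumulationParams,
                         rng: np.random.Generator, batch_size: int = 1):
    """Generate a batch of cue-accumulation trials.

    Returns ``(x, target, loss_mask)``: binary input spikes
    ``(batch, T, n_in)``, a one-hot class target ``(batch, T, 2)`` active
    only inside the recall window (class 0 = left majority), and the loss
    mask.  Cue sides are independent coin flips with probability
    ``p_left``; each cue elevates the Poisson rate of its side's channel
    group for ``cue_duration`` ms; the recall channel group fires during
    the recall window to signal decision time.
    """
    p = params
    T = p.n_steps
    n_side = p.n_channels_per_side
    steps_per_ms = 1.0 / p.dt

    sides = (rng.random((batch_size, p.n_cues)) >= p.p_left).astype(int)  # 0=left
    majority = (sides.sum(axis=1) > p.n_cues / 2).astype(int)

    rate = np.full((batch_size, T, p.n_in), p.noise_rate)
    for c in range(p.n_cues):
        start = int(round(c * (p.cue_duration + p.cue_gap) * steps_per_ms))
        stop = start + int(round(p.cue_duration * steps_per_ms))
        for b in range(batch_size):
            grp = sides[b, c] * n_side
            rate[b, start:stop, grp:grp + n_side] = p.cue_rate
    recall_start = T - int(round(p.recall_window * steps_per_ms))
    rate[:, recall_start:, 2 * n_side:] = p.cue_rate

    x = (rng.random(rate.shape) < rate * p.dt / 1000.0).astype(np.int8)

    loss_mask = np.zeros((batch_size, T))
    loss_mask[:, recall_start:] = 1.0
    target = np.zeros((batch_size, T, 2))
    target[np.arange(batch_size), :, majority] = 1.0
    target *= loss_mask[:, :, None]
    return x, target, loss_mask


class CueAccumulationTask:
    """Task adapter exposing ``sample_batch`` for the training loop."""

    n_classes = 2

    def __init__(self, params: CueAccumulationParams | None = None):
        self.params = params or CueAccumulationParams()

    @property
    def n_in(self) -> int:
        return self.params.n_in

    def sample_batch(self, rng: np.random.Generator, n: int):
        return gen_cue_accumulation(self.params, rng, n)


# ---------------------------------------------------------------------------
# Pattern regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatternRegressionParams:
    """A frozen random input raster and a sum-of-sinusoids target trace."""

    duration: int = 1000          # ms
    n_in: int = 20
    input_rate: float = 50.0      # Hz, frozen Poisson raster
    n_components: int = 3
    freq_range: tuple = (0.5, 5.0)  # Hz
    amp_range: tuple = (0.5, 2.0)
    dt: float = 1.0

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


def gen_pattern_regression(params: PatternRegressionParams,
                           rng: np.random.Generator):
    """One frozen (input, target) pair: the same raster is replayed every
    trial and the target is ``sum_m A_m sin(2 pi f_m t + phi_m)``."""
    p = params
    T = p.n_steps
    x = (rng.random((T, p.n_in)) < p.input_rate * p.dt / 1000.0).astype(np.int8)
    t_sec = np.arange(T) * p.dt / 1000.0
    y_star = np.zeros(T)
    for _ in range(p.n_components):
        f = rng.uniform(*p.freq_range)
        A = rng.uniform(*p.amp_range)
        phi = rng.uniform(0, 2 * np.pi)
        y_star += A * np.sin(2 * np.pi * f * t_sec + phi)
    loss_mask = np.ones(T)
    return x, y_star[:, None], loss_mask


class PatternRegressionTask:
    """Replays one frozen pattern-generation trial as every batch element."""

    def __init__(self, params: PatternRegressionParams, seed: int = 0):
        self.params = params
        rng = np.random.default_rng(seed)
        self._x, self._y_star, self._mask = gen_pattern_regression(params, rng)

    @property
    def n_in(self) -> int:
        return self.params.n_in

    def sample_batch(self, rng: np.random.Generator, n: int):
        return (np.repeat(self._x[None], n, axis=0),
                np.repeat(self._y_star[None], n, axis=0),
                np.repeat(self._mask[None], n, axis=0))


# ---------------------------------------------------------------------------
# Catch environment
# ---------------------------------------------------------------------------

ACTIONS = ("left", "stay", "right")
_MOVES = {0: -1, 1: 0, 2: +1}


@dataclass
class CatchEnvState:
    grid_width: int
    grid_height: int
    ball_col: int
    ball_row: int
    paddle_col: int
    done: bool = False


class CatchEnv:
    """A ball falls one row per step; the paddle must be under it at the
    bottom.  Reward +1 on interception, -1 otherwise, exactly once per
    episode.  Observations are one-hot spike groups for the ball column,
    ball row, and paddle column, each repeated for ``steps_per_cell``
    simulation steps.
    """

    def __init__(self, grid_width: int = 5, grid_height: int = 5,
                 steps_per_cell: int = 1, seed: int = 0):
        self.grid_width = grid_width
        self.grid_height = grid_height
        self.steps_per_cell = steps_per_cell
        self.rng = np.random.default_rng(seed)
        self.state: CatchEnvState | None = None

    @property
    def n_obs(self) -> int:
        return 2 * self.grid_width + self.grid_height

    @property
    def n_actions(self) -> int:
        return 3

    @property
    def episode_length(self) -> int:
        """Number of environment steps until the ball reaches the bottom."""
        return self.grid_height - 1

    def _observe(self) -> np.ndarray:
        s = self.state
        obs = np.zeros(self.n_obs, dtype=np.int8)
        obs[s.ball_col] = 1
        obs[self.grid_width + s.paddle_col] = 1
        obs[2 * self.grid_width + s.ball_row] = 1
        return obs

    def reset(self) -> np.ndarray:
        self.state = CatchEnvState(
            grid_width=self.grid_width, grid_height=self.grid_height,
            ball_col=int(self.rng.integers(self.grid_width)), ball_row=0,
            paddle_col=self.grid_width // 2)
        return self._observe()

    def step(self, action: int):
        """Advance one environment step; returns (obs, reward, done)."""
        s = self.state
        if s is None or s.done:
            raise RuntimeError("step() called on a finished episode; call reset()")
        if action not in (0, 1, 2):
            raise ValueError(f"action must be 0 (left), 1 (stay), or 2 (right); got {action}")
        s.paddle_col = int(np.clip(s.paddle_col + _MOVES[action], 0, self.grid_width - 1))
        s.ball_row += 1
        if s.ball_row >= self.grid_height - 1:
            s.done = True
            reward = 1.0 if s.paddle_col == s.ball_col else -1.0
        else:
            reward = 0.0
        return self._observe(), reward, s.done


def catch_env_step(state: CatchEnvState, action: int):
    """Pure-state variant of :meth:`CatchEnv.step` (no spike encoding)."""
    env = CatchEnv(state.grid_width, state.grid_height)
    env.state = state
    return env.step(action), env.state


def catch_random_baseline(grid_width: int = 5, grid_height: int = 5) -> float:
    """Exact expected return of the uniformly random policy, by
    enumerating every (ball column, action sequence) pair."""
    n_steps = grid_height - 1
    total = 0.0
    count = 0
    for ball in range(grid_width):
        for seq in itertools.product((0, 1, 2), repeat=n_steps):
            paddle = grid_width // 2
            for a in seq:
                paddle = int(np.clip(paddle + _MOVES[a], 0, grid_width - 1))
            total += 1.0 if paddle == ball else -1.0
            count += 1
    return total / count


def catch_best_return(grid_width: int, grid_height: int, ball_col: int,
                      paddle_col: int | None = None) -> float:
    """Best achievable return for a given spawn configuration, by
    exhaustive search over action sequences (a tiny certification oracle)."""
    n_steps = grid_height - 1
    start = grid_width // 2 if paddle_col is None else paddle_col
    for seq in itertools.product((0, 1, 2), repeat=n_steps):
        paddle = start
        for a in seq:
            paddle = int(np.clip(paddle + _MOVES[a], 0, grid_width - 1))
        if paddle == ball_col:
            return 1.0
    return -1.0
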