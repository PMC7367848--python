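"""Network configuration for recurrent spiking networks.

All dynamical constants of the simulated network live here: population
sizes, membrane/adaptation/readout time constants, the firing threshold,
the adaptive-threshold coupling, the surrogate-derivative dampening, and
the refractory period.  Decay factors are always derived from the time
constants as ``exp(-dt/tau)`` and never stored independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace


class ConfigurationError(ValueError):
    """Raised when a network or experiment configuration is invalid."""


@dataclass(frozen=True)
class NetworkConfig:
    """Architectural and dynamical constants of a recurrent spiking network.

    Parameters
    ----------
    n_in, n_rec, n_out:
        Number of input channels, recurrent neurons, and leaky readouts.
    n_adaptive:
        Number of neurons with an adaptive (spike-frequency-adapting)
        threshold.  By convention these are the *last* ``n_adaptive`` rows
        of the recurrent population; the remaining rows are plain LIF.
    dt:
        Simulation time step in ms.
    tau_m, tau_a, tau_out:
        Membrane, threshold-adaptation, and readout time constants (ms).
    v_th:
        Baseline firing threshold (potential units).
    beta:
        Coupling of the adaptation variable into the threshold
        (dimensionless); the effective threshold is ``v_th + beta * a``.
    gamma_pd:
        Dampening factor of the triangular pseudo-derivative.
    n_refractory:
        Number of steps after a spike during which the neuron cannot fire
        and its pseudo-derivative is zero.
    delay:
        Spike transmission delay between recurrent neurons, in steps.
    v0, a0, y0:
        Initial membrane potential, adaptation variable, and readout value
        at trial start (scalars, broadcast to all units).
    seed:
        Base seed for weight initialization when none is passed explicitly.
    """

    n_in: int
    n_rec: int
    n_out: int
    n_adaptive: int = 0
    dt: float = 1.0
    tau_m: float = 20.0
    tau_a: float = 2000.0
    tau_out: float = 20.0
    v_th: float = 1.0
    beta: float = 0.07
    gamma_pd: float = 0.3
    n_refractory: int = 3
    delay: int = 1
    v0: float = 0.0
    a0: float = 0.0
    y0: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_in < 0 or self.n_rec <= 0 or self.n_out <= 0:
            problems.append("population sizes must satisfy n_in >= 0, n_rec > 0, n_out > 0")
        if not 0 <= self.n_adaptive <= self.n_rec:
            problems.append(f"n_adaptive={self.n_adaptive} must lie in [0, n_rec={self.n_rec}]")
        if self.dt <= 0:
            problems.append(f"dt={self.dt} must be positive")
        for name in ("tau_m", "tau_a", "tau_out"):
            if getattr(self, name) <= 0:
                problems.append(f"{name}={getattr(self, name)} must be positive")
        if self.v_th <= 0:
            problems.append(f"v_th={self.v_th} must be positive")
        if self.gamma_pd < 0:
            problems.append(f"gamma_pd={self.gamma_pd} must be non-negative")
        if self.n_refractory < 0:
            problems.append(f"n_refractory={self.n_refractory} must be non-negative")
        if self.delay < 1:
            problems.append(f"delay={self.delay} must be at least 1 step")
        if problems:
            raise ConfigurationError("; ".join(problems))

    # --- derived decay factors -------------------------------------------

    @property
    def alpha(self) -> float:
        """Membrane decay ``exp(-dt/tau_m)``, in (0, 1)."""
        return math.exp(-self.dt / self.tau_m)

    @property
    def rho(self) -> float:
        """Adaptation decay ``exp(-dt/tau_a)``, in (0, 1)."""
        return math.exp(-self.dt / self.tau_a)

    @property
    def kappa(self) -> float:
        """Readout decay ``exp(-dt/tau_out)``, in (0, 1)."""
        return math.exp(-self.dt / self.tau_out)

    @property
    def n_regular(self) -> int:
        """Number of non-adapting (plain LIF) neurons."""
        return self.n_rec - self.n_adaptive

    def beta_vector(self, dtype=float):
        """Per-neuron threshold coupling: 0 for LIF rows, ``beta`` for ALIF rows."""
        import numpy as np

        out = np.zeros(self.n_rec, dtype=dtype)
        out[self.n_regular:] = self.beta
        return out

    def with_(self, **changes) -> "NetworkConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def decay_constants(config: NetworkConfig) -> tuple[float, float, float]:
    """Return the decay factors ``(alpha, rho, kappa)`` of a configuration.

    Each equals ``exp(-dt/tau)`` for the membrane, adaptation, and readout
    time constants respectively, and lies strictly inside (0, 1).
    """
    return config.alpha, config.rho, config.kappa
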