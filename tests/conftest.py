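import numpy as np
import pytest

from eprop import NetworkConfig, initialize_weights


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small mixed LIF/ALIF network used across unit tests."""
    return NetworkConfig(n_in=3, n_rec=6, n_out=2, n_adaptive=3,
                         tau_m=20.0, tau_a=150.0, tau_out=10.0,
                         v_th=0.5, beta=0.07, n_refractory=2, seed=7)


@pytest.fixture
def small_weights(small_config, rng):
    return initialize_weights(small_config, rng, feedback="symmetric", gain=1.0)


def random_spikes(rng, T, n, p=0.3):
    return (rng.random((T, n)) < p).astype(np.int8)
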