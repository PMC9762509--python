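import numpy as np
import pytest

from gatedrnn import NetworkParams, make_network, simulate


@pytest.fixture(scope="session")
def chaotic_net():
    """Moderate-size network in the chaotic phase (g_h=3, open gates)."""
    return make_network(NetworkParams(n_units=500, g_h=3.0, seed=5))


@pytest.fixture(scope="session")
def chaotic_traj(chaotic_net):
    """Relaxed chaotic trajectory reused by moment/correlator/spectra tests."""
    return simulate(chaotic_net, t_final=200.0, record_every=4)


@pytest.fixture(scope="session")
def small_mixed_net():
    """Small network with all channels active (finite gate gains, biases)."""
    return make_network(NetworkParams(n_units=20, g_h=2.0, alpha_z=2.0,
                                      alpha_r=3.0, beta_z=0.3, beta_r=-0.2,
                                      tau_z=0.7, tau_r=1.5, seed=9))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
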