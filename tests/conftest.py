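import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from izhcortex.config import make_fixture
from izhcortex.network import (
    ConnectionSpec,
    GroupSpec,
    NetworkConfig,
    NoiseSpec,
    RunSpec,
)
from izhcortex.neuron import SpikingType


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def tiny_config():
    """2 groups x 10 neurons, one excitatory and one inhibitory phenotype."""
    return make_fixture(2, 10, seed=7)


@pytest.fixture
def small_config():
    """2 groups x 50 neurons, the standard smoke-run circuit."""
    return make_fixture(2, 50, seed=7)


def quiet_rs_config(n=20, weight=0.0, sigma=0.0, duration=150.0, i_ext=0.0, seed=3):
    """Two regular-spiking pyramidal groups; RS rests stably at its reset
    potential, so with zero noise and weight the circuit stays silent."""
    groups = (
        GroupSpec("RS_a", "pyramidal", "L2/3", n, SpikingType.RS, "AMPA"),
        GroupSpec("RS_b", "pyramidal", "L4", n, SpikingType.RS, "AMPA"),
    )
    connections = tuple(
        ConnectionSpec(a, b, sparseness=0.1, weight=weight)
        for a in ("RS_a", "RS_b")
        for b in ("RS_a", "RS_b")
    )
    return NetworkConfig(
        groups=groups,
        connections=connections,
        noise=NoiseSpec(sigma_exc=sigma, sigma_inh=sigma),
        run=RunSpec(duration_ms=duration, seed=seed, i_ext=i_ext),
    )
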