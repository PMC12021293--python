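import numpy as np
import pytest

from metaplast.networks import build_network, desk_topology


@pytest.fixture(scope="session")
def desk_vogels():
    """One desk-scale Vogels network shared by read-only tests."""
    topo = desk_topology("vogels")
    topology, state = build_network("vogels", topo, seed=11)
    return topo, topology, state


@pytest.fixture(scope="session")
def desk_zenke():
    topo = desk_topology("zenke")
    topology, state = build_network("zenke", topo, seed=12)
    return topo, topology, state


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
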