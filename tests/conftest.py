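import numpy as np
import pytest

import fibronet as fn
from fibronet.injury import fixture_networks


@pytest.fixture(scope="session")
def small_net():
    """A ~200-spring regularized Voronoi network, fixed seed."""
    return fn.generate_voronoi_network(100, rng_seed=7)


@pytest.fixture(scope="session")
def raw_net():
    """Raw clipped tessellation (no regularization), fixed seed."""
    return fn.generate_voronoi_network(
        200, rng_seed=13, lloyd_iterations=0, min_edge_frac=0.0
    )


@pytest.fixture(scope="session")
def fixtures():
    return fixture_networks()


@pytest.fixture(scope="session")
def params():
    return fn.default_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
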