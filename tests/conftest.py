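import numpy as np
import pytest
from hypothesis import settings

import culturenet as cn

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic study world shared by read-only tests."""
    return cn.make_world(n_tips=24, n_colonies=8, seed=11)


@pytest.fixture(scope="session")
def ring100():
    """Row-normalized ring lattice, the low-bias reference topology."""
    from culturenet.synthetic_data import ring_lattice_weights
    return ring_lattice_weights(100, 4)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_nodes(n, prefix="t"):
    return cn.NodeSet(ids=tuple(f"{prefix}{i}" for i in range(n)))
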