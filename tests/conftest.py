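import numpy as np
import pytest

from rrna_mosaic import SimulationConfig, make_parent_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20190802)


@pytest.fixture(scope="session")
def parent_pair():
    """A host/donor pair at study-like divergence (1500 bp, 85.9% identity)."""
    return make_parent_pair(1500, 85.9, gc=60.0, seed=11)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)
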