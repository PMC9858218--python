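import numpy as np
import pytest

from genefam.synthetic_data import default_world


@pytest.fixture(scope="session")
def world():
    """One shared default synthetic world (seed 1)."""
    return default_world(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230109)
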