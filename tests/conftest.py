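import numpy as np
import pytest

from hnntm.synthetic import toy_topology_model


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def toy_model():
    return toy_topology_model()
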