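import numpy as np
import pytest
from hypothesis import settings

from mmdma import ModalityMatrix, PairConfig, make_pair

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_pair(rng):
    """A 30-cell pair with px=5, py=4 used for primal/dual identities."""
    x = ModalityMatrix(rng.standard_normal((30, 5)))
    y = ModalityMatrix(rng.standard_normal((30, 4)))
    return x, y


@pytest.fixture(scope="session")
def branch_pair():
    """Default synthetic branch pair (n=300, d_latent=5, px=50, py=40)."""
    return make_pair(PairConfig(seed=0))
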