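import numpy as np
import pytest

from bonebed.fixture import build_vm4_fixture
from bonebed.synthetic import simulate_site


@pytest.fixture(scope="session")
def vm4():
    """The deterministic published-marginals assemblage (built once)."""
    return build_vm4_fixture()


@pytest.fixture(scope="session")
def default_site():
    """One default two-band synthetic site."""
    return simulate_site(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
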