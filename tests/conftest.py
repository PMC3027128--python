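import numpy as np
import pytest

from scatterdose.phantom import build_phantom
from scatterdose.physics import default_materials


@pytest.fixture(scope="session")
def materials():
    return default_materials()


@pytest.fixture(scope="session")
def phantom():
    """The default chest phantom (expensive enough to share across tests)."""
    return build_phantom()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
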