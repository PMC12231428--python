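import numpy as np
import pytest

from ecpredict.atlas import NETWORK_LABELS, NetworkAtlas
from ecpredict.synthetic import make_atlas


@pytest.fixture
def tiny_atlas() -> NetworkAtlas:
    """Seven networks, one parcel each."""
    return make_atlas({lab: 1 for lab in NETWORK_LABELS})


@pytest.fixture
def small_atlas() -> NetworkAtlas:
    """28 parcels, four per network."""
    return make_atlas({lab: 4 for lab in NETWORK_LABELS})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
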