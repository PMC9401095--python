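import numpy as np
import pytest

from ratcapsnet.config import NetworkConfig
from ratcapsnet.types import FeatureMap


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """Smallest full-featured architecture: 2 stages, one PFE tap."""
    return NetworkConfig(base_width_n=4, pfe_width_rho=2, num_stages=2,
                         pfe_stages=(2,), dense_sizes=(8, 6), num_classes=3,
                         input_hw=(8, 8), seed=7)


@pytest.fixture
def small_map(rng):
    return FeatureMap(rng.random((8, 8, 4)))
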