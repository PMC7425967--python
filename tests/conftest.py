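import numpy as np
import pytest

from mammofusion.backbone import BackboneSpec
from mammofusion.phantoms import generate_dataset


SMALL = dict(input_size=64, stem_channels=8, block_sizes=(2, 2),
             growth_rate=8, reduction_ratio=4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Reduced backbone for desk-scale training tests."""
    return BackboneSpec(**SMALL)


@pytest.fixture(scope="session")
def phantom_cases():
    """A small balanced phantom dataset shared across tests (read-only)."""
    return generate_dataset(12, seed=7, image_size=64)
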