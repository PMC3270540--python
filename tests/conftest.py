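import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from cooctex.image_prep import QuantizedMap


@pytest.fixture
def rng():
    return np.random.default_rng(20417)


@pytest.fixture
def random_map_factory():
    """Seeded random label maps with optional random validity masks."""

    def factory(seed: int, height: int, width: int, levels: int, masked: bool = False):
        r = np.random.default_rng(seed)
        labels = r.integers(0, levels, size=(height, width))
        if masked:
            mask = r.random((height, width)) < 0.85
        else:
            mask = np.ones((height, width), dtype=bool)
        return QuantizedMap(labels=labels, levels=levels, valid_mask=mask)

    return factory


@pytest.fixture
def random_image_factory():
    def factory(seed: int, height: int = 50, width: int = 50, low: int = 0, high: int = 256):
        r = np.random.default_rng(seed)
        return r.integers(low, high, size=(height, width)).astype(np.uint8)

    return factory
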