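import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_image(rng):
    """Seeded 12x12 8-bit image, large enough for one R=3 window pass."""
    return rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
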