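import numpy as np
import pytest

from panoscape.rasters import HAMMER, SphericalRaster


@pytest.fixture
def random_rasters():
    """Factory for seeded random small categorical rasters (fully valid)."""

    def make(n: int, size: int = 16, n_classes: int = 4, seed: int = 0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            vals = rng.integers(0, n_classes, size=(size, size))
            out.append(
                SphericalRaster(vals, HAMMER, np.ones((size, size), dtype=bool))
            )
        return out

    return make
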