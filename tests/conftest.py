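import numpy as np
import pytest

from peapheno.image_traits import PlantMask


@pytest.fixture
def rng():
    return np.random.default_rng(20231024)


def random_mask(rng: np.random.Generator, shape=(12, 12), max_pixels=50) -> PlantMask:
    """Sparse random mask with at most max_pixels plant pixels."""
    n = int(rng.integers(0, max_pixels + 1))
    grid = np.zeros(shape, dtype=bool)
    if n:
        idx = rng.choice(shape[0] * shape[1], size=min(n, shape[0] * shape[1]), replace=False)
        grid.flat[idx] = True
    return PlantMask(grid)
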