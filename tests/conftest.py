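import numpy as np
import pytest

from reefscape.grid import DEMGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def flat_grid():
    """12 m x 2 m flat transect at 0.5 m elevation, 3 cm pixels."""
    return DEMGrid(np.full((67, 400), 0.5), 0.03)


@pytest.fixture
def rough_grid(rng):
    """Seeded random rough surface, 4 m x 2 m at 5 cm pixels."""
    return DEMGrid(0.1 * rng.standard_normal((40, 80)), 0.05)


def make_random_grid(seed: int, nrows: int, ncols: int, cell: float = 0.05,
                     scale: float = 0.1) -> DEMGrid:
    g = np.random.default_rng(seed)
    return DEMGrid(scale * g.standard_normal((nrows, ncols)), cell)
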