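import numpy as np
import pytest

from parashift.grids import ClimateStack, make_grid


@pytest.fixture
def small_grid():
    """10x10 one-degree grid."""
    return make_grid((0.0, 40.0, 10.0, 50.0), 1.0)


@pytest.fixture
def masked_stack(small_grid):
    """Two-layer stack with a 3-cell nodata hole."""
    rng = np.random.default_rng(42)
    mask = np.ones(small_grid.shape, dtype=bool)
    mask[0, 0] = mask[5, 5] = mask[9, 9] = False
    layers = {
        "bio1": rng.standard_normal(small_grid.shape),
        "bio12": rng.standard_normal(small_grid.shape),
    }
    return ClimateStack(grid=small_grid, layers=layers, mask=mask)
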