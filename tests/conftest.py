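import numpy as np
import pytest

from gliamig.coloc import LabelMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_label_grid(rng, shape=(24, 24), n_seeds=4):
    """Small random label image: a few rectangular cells that may touch."""
    grid = np.zeros(shape, dtype=np.int32)
    label = 0
    for _ in range(n_seeds):
        h = int(rng.integers(2, 6))
        w = int(rng.integers(2, 6))
        y = int(rng.integers(0, shape[0] - h))
        x = int(rng.integers(0, shape[1] - w))
        patch = grid[y : y + h, x : x + w]
        if (patch != 0).any():
            continue
        label += 1
        patch[:] = label
    return grid


@pytest.fixture
def square_cell_mask():
    """Single 3x3 square cell centered in a 9x9 grid."""
    grid = np.zeros((9, 9), dtype=np.int32)
    grid[3:6, 3:6] = 1
    return LabelMask(grid)
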