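import numpy as np
import pytest

from canopyaroma.gap import BinaryCanopyMask
from canopyaroma.synthetic import (
    CROWN_RGB,
    SKY_RGB,
    SOIL_RGB,
    load_tree_summary,
)


@pytest.fixture(scope="session")
def tree_summary():
    """Per-tree canopy means/SD of the 24 field trees (packaged fixture)."""
    return load_tree_summary()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_mask_with_cell_gap_fractions(fractions, cell=10):
    """2x2-grid mask whose four cells have the given gap fractions.

    Gap pixels fill each cell from its first flat index, which keeps them
    contiguous per cell; ground truth is the exact per-cell count.
    """
    assert len(fractions) == 4
    pixels = np.ones((2 * cell, 2 * cell), dtype=bool)
    for idx, frac in enumerate(fractions):
        i, j = divmod(idx, 2)
        block = np.ones(cell * cell, dtype=bool)
        block[: int(round(frac * cell * cell))] = False
        pixels[i * cell : (i + 1) * cell, j * cell : (j + 1) * cell] = block.reshape(
            cell, cell
        )
    return BinaryCanopyMask(pixels)


def rgb_tile(color, shape=(40, 40), noise=0.0, seed=0):
    """Uniform (optionally noisy) RGB tile of one nominal colour."""
    rng = np.random.default_rng(seed)
    tile = np.broadcast_to(np.asarray(color, float), shape + (3,)).copy()
    if noise:
        tile = tile + rng.normal(0, noise, tile.shape)
    return np.clip(tile, 0, 255).astype(np.uint8)


@pytest.fixture()
def sky_tile():
    return rgb_tile(SKY_RGB)


@pytest.fixture()
def foliage_tile():
    return rgb_tile(CROWN_RGB)


@pytest.fixture()
def soil_tile():
    return rgb_tile(SOIL_RGB)
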