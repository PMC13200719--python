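import numpy as np
import pytest

from dimple.msi_io import Mask, MSIGrid, PixelSpectrum
from dimple.preprocess import run_preprocess
from dimple.synthetic import generate_root_msi


def make_grid(entries, rows, cols, **meta):
    """Build an MSIGrid from {(row, col): ([mz...], [intensity...])}."""
    grid = MSIGrid.empty(rows, cols, **meta)
    for (r, c), (mz, inten) in entries.items():
        grid[r, c] = PixelSpectrum(np.asarray(mz, float), np.asarray(inten, float))
    return grid


@pytest.fixture(scope="session")
def default_fixture():
    """The standard synthetic acquisition: 100x24 grid, 4 axial pattern
    classes x 5 channels, 5 background-only, 3 sparse, 1 ppm jitter, seed 0."""
    grid, gt = generate_root_msi(seed=0)
    return grid, gt


@pytest.fixture(scope="session")
def default_processed(default_fixture):
    grid, gt = default_fixture
    hsi, peakset = run_preprocess(grid, gt.mask)
    return grid, gt, hsi, peakset


@pytest.fixture
def small_mask():
    return Mask(np.ones((4, 4), dtype=bool))
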