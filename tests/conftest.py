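import numpy as np
import pytest

import latcov as lc


@pytest.fixture
def even_grid():
    """8x6x6 grid, 2 mm voxels, x centers at +/-1..+/-7 mm (no midline)."""
    return lc.build_grid((8, 6, 6))


@pytest.fixture
def midline_grid():
    """17x13x13 grid, 2 mm voxels, even-mm centers including an x = 0 column."""
    return lc.build_grid((17, 13, 13))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_pair_image(grid, left_mm, left_value, right_value, fill=0.0, subject_id="s"):
    """Image with given values at a left-hemisphere voxel and its homologue."""
    values = np.full(grid.dims, float(fill))
    v = tuple(grid.mm_to_voxel(left_mm))
    h = lc.homologue(grid, v)
    values[v] = left_value
    values[h] = right_value
    return lc.ContrastImage(grid=grid, values=values, subject_id=subject_id), v, h
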