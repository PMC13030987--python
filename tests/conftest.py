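import numpy as np
import pytest

from cubicell import Calibration, CubeGrid, neighbor_graph


@pytest.fixture
def calibration():
    return Calibration(pixel_size_x=1.0, pixel_size_y=1.0, z_step=5.0)


@pytest.fixture
def grid_and_graph():
    """Factory: CubeGrid + NeighborGraph from a 3D counts array (optional mask)."""

    def make(counts, mask=None, cube_size=45.0):
        counts = np.asarray(counts, dtype=np.int64)
        grid = CubeGrid.from_counts(counts, cube_size=cube_size, mask=mask)
        return grid, neighbor_graph(grid)

    return make
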