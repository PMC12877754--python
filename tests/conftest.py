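import numpy as np
import pytest

from gaudiloci import (
    BinGrid,
    ContactMatrix,
    GenomicRegion,
    SpatialLayout,
    make_bin_grid,
)


@pytest.fixture
def small_grid() -> BinGrid:
    """Four 5 kb bins on a toy chromosome."""
    return make_bin_grid(GenomicRegion("chr1", 0, 20_000), 5000)


@pytest.fixture
def collinear_layout():
    """Five bins on a line with unit spacing (mean interbin distance 1)."""
    grid = make_bin_grid(GenomicRegion("chr1", 0, 25_000), 5000)
    xy = np.column_stack([np.arange(5, dtype=float), np.zeros(5)])
    return SpatialLayout(grid, xy, mean_interbin=1.0, stress=0.0)


def make_matrix(values, resolution=5000, chrom="chr1") -> ContactMatrix:
    """Contact matrix from a dense array on an auto-sized grid."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    grid = make_bin_grid(GenomicRegion(chrom, 0, n * resolution), resolution)
    return ContactMatrix(grid, values)


@pytest.fixture
def matrix_factory():
    return make_matrix
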