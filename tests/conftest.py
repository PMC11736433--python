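import numpy as np
import pytest
import scipy.sparse as sp

from enetkit import (
    CellByFeatureMatrix,
    GenomicInterval,
    PeakSet,
    SimulationConfig,
    simulate_accessibility,
)


@pytest.fixture(scope="session")
def small_sim():
    """Modules-only simulation shared by topology/linking tests."""
    cfg = SimulationConfig(n_cells=2000, n_genes=6, n_affected_genes=0, seed=4)
    return simulate_accessibility(cfg)


@pytest.fixture()
def toy_peaks():
    return PeakSet(
        [
            GenomicInterval("chr1", 1_000, 1_500, "A"),
            GenomicInterval("chr1", 4_000, 4_500, "B"),
            GenomicInterval("chr1", 8_000, 8_500, "C"),
            GenomicInterval("chr2", 1_000, 1_500, "D"),
        ]
    )


def make_matrix(arr, cells=None, features=None):
    arr = np.asarray(arr, dtype=float)
    cells = cells or [f"c{i}" for i in range(arr.shape[0])]
    features = features or [f"f{j}" for j in range(arr.shape[1])]
    return CellByFeatureMatrix(cells, features, sp.csr_matrix(arr))


@pytest.fixture()
def matrix_factory():
    return make_matrix
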