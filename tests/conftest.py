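import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from snapkit import synthetic
from snapkit.core_matrix import (
    CellByBinCounts,
    CellByBinMatrix,
    binarize,
    drop_zero_coverage_cells,
    make_bins,
)


@pytest.fixture(scope="session")
def three_pop_dataset():
    """300 cells, 3 populations, modest coverage; shared across modules."""
    profiles = synthetic.make_profiles(3, m_bins=2000, seed=11)
    return synthetic.simulate_cells(profiles, 100, coverage_range=(500, 2000),
                                    seed=11)


@pytest.fixture(scope="session")
def three_pop_matrix(three_pop_dataset):
    return drop_zero_coverage_cells(binarize(three_pop_dataset.counts))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def binary_matrix_from_dense(dense, bin_size=100):
    """Wrap a dense 0/1 array as a CellByBinMatrix on one toy chromosome."""
    dense = np.asarray(dense)
    n, m = dense.shape
    bins = make_bins({"chr1": m * bin_size}, bin_size)
    return CellByBinMatrix(
        X=sp.csr_matrix(dense.astype(np.int8)),
        cell_barcodes=[f"c{i}" for i in range(n)],
        bin_coords=bins,
    )


def counts_from_dense(dense, bin_size=100):
    dense = np.asarray(dense)
    n, m = dense.shape
    bins = make_bins({"chr1": m * bin_size}, bin_size)
    return CellByBinCounts(
        counts=sp.csr_matrix(dense.astype(np.int64)),
        cell_barcodes=[f"c{i}" for i in range(n)],
        bin_coords=bins,
        bin_size=bin_size,
    )


def write_fragments_file(tmp_path, rows, name="frags.tsv"):
    path = tmp_path / name
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    return path


@pytest.fixture()
def promoters_bed():
    return pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [1000, 5000, 0],
        "end": [2000, 6000, 500],
    })
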