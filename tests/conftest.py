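import numpy as np
import pytest

from cfcnv.covmatrix import CoverageMatrix
from cfcnv.windows import ChromSizes, make_windows


@pytest.fixture
def toy_chrom_sizes():
    return ChromSizes([("chrA", 25_000), ("chrB", 8_000)])


@pytest.fixture
def toy_windows(toy_chrom_sizes):
    return make_windows(toy_chrom_sizes, 10_000)


@pytest.fixture
def chrom_sizes_file(tmp_path):
    path = tmp_path / "toy.chrom.sizes"
    path.write_text("chrA\t25000\nchrB\t8000\n")
    return path


def make_matrix(values, labels=None, stage="normalized", window_indices=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if labels is None:
        labels = np.arange(n) % 2
    if window_indices is None:
        window_indices = np.arange(m)
    return CoverageMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        window_indices=np.asarray(window_indices),
        values=values,
        labels=np.asarray(labels),
        stage=stage,
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
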