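import numpy as np
import pytest
import scipy.sparse as sp

from enhancon.intervals import GenomicInterval, PeakSet
from enhancon.matrix import BinaryAccessibilityMatrix


def make_peaks(n: int, chrom: str = "chr1", width: int = 400, spacing: int = 2000) -> PeakSet:
    """Evenly spaced non-overlapping peaks."""
    return PeakSet(
        [GenomicInterval(chrom, i * spacing, i * spacing + width) for i in range(n)]
    )


def make_bam(values, cell_type: str = "typeA", peak_set: PeakSet | None = None):
    """Binary accessibility matrix from a dense 0/1 array (peaks x cells)."""
    values = np.asarray(values, dtype=np.int8)
    if peak_set is None:
        peak_set = make_peaks(values.shape[0])
    return BinaryAccessibilityMatrix(
        values=sp.csr_matrix(values),
        peak_set=peak_set,
        cell_ids=[f"cell{j}" for j in range(values.shape[1])],
        cell_type=cell_type,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
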