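"""Binary accessibility matrices: binarization, dataset merging, and QC.

scATAC-seq signal is effectively binary per cell: a peak is "open" in a
cell if at least one read fell in it, "closed" otherwise. Binarizing makes
datasets of different sequencing depths comparable before integration.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .intervals import GenomicInterval, PeakSet

__all__ = [
    "BinaryAccessibilityMatrix",
    "QCReport",
    "EmptyMatrixError",
    "DEFAULT_CHROM_PATTERN",
    "binarize",
    "merge_datasets",
    "qc_filter",
    "split_by_cell_type",
]

logger = logging.getLogger(__name__)

# Canonical chromosomes: autosomes, X/Y, mitochondrial, fly arms, and the
# simulator's synthetic chromosome "chrS". Scaffolds and patches
# (chr1_random, chrUn_*, *_hap*, *_alt) never match.
DEFAULT_CHROM_PATTERN = r"^(chr)?(\d+|X|Y|M|MT|S|2L|2R|3L|3R|4)$"


class EmptyMatrixError(ValueError):
    """All cells or all peaks were removed by quality control."""


@dataclass
class BinaryAccessibilityMatrix:
    """Peaks x cells 0/1 matrix for one cell type.

    ``values`` is a scipy sparse matrix with entries in {0, 1}; row i is
    ``peak_set[i]``, column j is ``cell_ids[j]``. ``dataset_of_cell`` tracks
    the source dataset of every cell.
    """

    values: sp.csr_matrix
    peak_set: PeakSet
    cell_ids: list[str]
    cell_type: str
    dataset_of_cell: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.peak_set), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.peak_set)} peaks x {len(self.cell_ids)} cells"
            )
        if not self.dataset_of_cell:
            self.dataset_of_cell = ["dataset0"] * len(self.cell_ids)
        if len(self.dataset_of_cell) != len(self.cell_ids):
            raise ValueError("dataset_of_cell must align with cell_ids")
        if self.values.nnz:
            d = self.values.data
            if d.min() < 0 or d.max() > 1:
                raise ValueError("matrix entries must be 0 or 1")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_set)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def peaks_per_cell(self) -> np.ndarray:
        """Number of open peaks in each cell."""
        return np.asarray(self.values.sum(axis=0)).ravel().astype(np.int64)

    def cells_per_peak(self) -> np.ndarray:
        """Number of cells open at each peak."""
        return np.asarray(self.values.sum(axis=1)).ravel().astype(np.int64)

    def subset(self, peak_mask=None, cell_mask=None) -> "BinaryAccessibilityMatrix":
        vals = self.values
        ps = self.peak_set
        cids = self.cell_ids
        dsets = self.dataset_of_cell
        if peak_mask is not None:
            peak_mask = np.asarray(peak_mask, dtype=bool)
            vals = vals[peak_mask]
            ps = ps.subset(peak_mask)
        if cell_mask is not None:
            cell_mask = np.asarray(cell_mask, dtype=bool)
            vals = vals[:, cell_mask]
            cids = [c for c, keep in zip(cids, cell_mask) if keep]
            dsets = [d for d, keep in zip(dsets, cell_mask) if keep]
        return BinaryAccessibilityMatrix(
            values=sp.csr_matrix(vals),
            peak_set=ps,
            cell_ids=cids,
            cell_type=self.cell_type,
            dataset_of_cell=dsets,
        )


def binarize(
    counts: sp.spmatrix | np.ndarray,
    peak_set: PeakSet,
    cell_ids: Sequence[str],
    cell_type: str,
    dataset_id: str = "dataset0",
) -> BinaryAccessibilityMatrix:
    """Binarize a count matrix: 1 wherever at least one read, else 0."""
    counts = sp.csr_matrix(counts)
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("negative count entry")
    binary = counts.copy()
    binary.data = (binary.data >= 1).astype(np.int8)
    binary.eliminate_zeros()
    return BinaryAccessibilityMatrix(
        values=binary,
        peak_set=peak_set,
        cell_ids=list(cell_ids),
        cell_type=cell_type,
        dataset_of_cell=[dataset_id] * counts.shape[1],
    )


def _merge_interval_union(
    peak_sets: Sequence[PeakSet], merge_gap: int
) -> tuple[PeakSet, list[np.ndarray]]:
    """Union all peaks into maximal merged intervals.

    Returns the merged PeakSet and, per input set, the index of the merged
    peak each source peak maps to. Book-ended or gap<=merge_gap intervals
    merge.
    """
    records = []  # (chrom, start, end, source_set, source_row)
    for si, ps in enumerate(peak_sets):
        for ri, p in enumerate(ps):
            records.append((p.chrom, p.start, p.end, si, ri))
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    merged: list[GenomicInterval] = []
    mappings = [np.full(len(ps), -1, dtype=np.intp) for ps in peak_sets]
    cur_chrom, cur_start, cur_end = None, None, None
    members: list[tuple[int, int]] = []

    def flush():
        if cur_chrom is None:
            return
        merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
        mi = len(merged) - 1
        for si, ri in members:
            mappings[si][ri] = mi

    for chrom, start, end, si, ri in records:
        if chrom == cur_chrom and start <= cur_end + merge_gap:
            cur_end = max(cur_end, end)
        else:
            flush()
            cur_chrom, cur_start, cur_end = chrom, start, end
            members = []
        members.append((si, ri))
    flush()
    return PeakSet(merged), mappings


def merge_datasets(
    matrices: Sequence[BinaryAccessibilityMatrix],
    merge_gap: int = 0,
    min_dataset_peaks: int = 200,
) -> BinaryAccessibilityMatrix:
    """Merge datasets of one cell type over a unified interval-union PeakSet.

    A cell is open at a merged peak iff it was open at any constituent
    source peak; columns are the disjoint union of input columns. Barcodes
    duplicated across datasets are suffixed with their dataset id.
    Datasets whose own PeakSet has fewer than ``min_dataset_peaks`` peaks
    are rejected as irregular.
    """
    if not matrices:
        raise ValueError("no datasets to merge")
    cell_types = {m.cell_type for m in matrices}
    if len(cell_types) != 1:
        raise ValueError(f"conflicting cell_type labels: {sorted(cell_types)}")
    for m in matrices:
        if m.n_peaks < min_dataset_peaks:
            raise ValueError(
                f"irregular dataset with {m.n_peaks} < {min_dataset_peaks} peaks"
            )
    merged_set, mappings = _merge_interval_union(
        [m.peak_set for m in matrices], merge_gap
    )
    blocks = []
    for m, mapping in zip(matrices, mappings):
        # projection matrix: merged x source, OR-accumulate then clip
        proj = sp.csr_matrix(
            (
                np.ones(len(mapping), dtype=np.int8),
                (mapping, np.arange(len(mapping))),
            ),
            shape=(len(merged_set), m.n_peaks),
        )
        block = proj @ m.values
        block.data = (block.data >= 1).astype(np.int8)
        blocks.append(block)
    values = sp.hstack(blocks, format="csr")

    cell_ids: list[str] = []
    datasets: list[str] = []
    seen: set[str] = set()
    for m in matrices:
        for bc, ds in zip(m.cell_ids, m.dataset_of_cell):
            name = bc if bc not in seen else f"{bc}.{ds}"
            k = 1
            while name in seen:
                name = f"{bc}.{ds}.{k}"
                k += 1
            seen.add(name)
            cell_ids.append(name)
            datasets.append(ds)
    return BinaryAccessibilityMatrix(
        values=values,
        peak_set=merged_set,
        cell_ids=cell_ids,
        cell_type=matrices[0].cell_type,
        dataset_of_cell=datasets,
    )


@dataclass
class QCReport:
    """Counts of cells/peaks removed per reason during quality control."""

    cells_low_peaks: int = 0
    peaks_zero_signal: int = 0
    peaks_bad_chrom: int = 0
    cell_types_dropped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("cells_removed_low_peaks", self.cells_low_peaks),
            ("peaks_removed_zero_signal", self.peaks_zero_signal),
            ("peaks_removed_bad_chromosome", self.peaks_bad_chrom),
            ("cell_types_dropped", len(self.cell_types_dropped)),
        ]
        return pd.DataFrame(rows, columns=["reason", "count"])


def qc_filter(
    matrix: BinaryAccessibilityMatrix,
    min_peaks_per_cell: int = 200,
    allowed_chrom_pattern: str = DEFAULT_CHROM_PATTERN,
) -> tuple[BinaryAccessibilityMatrix, QCReport]:
    """Apply the standard QC filters, iterated to a fixed point.

    Removes peaks on non-canonical chromosomes, then alternates removing
    cells with fewer than ``min_peaks_per_cell`` open peaks and peaks open
    in zero cells until nothing changes (a cell removal can zero out a peak
    and vice versa, so one pass is not enough).
    """
    report = QCReport()
    pat = re.compile(allowed_chrom_pattern)
    chrom_ok = np.array([bool(pat.match(c)) for c in matrix.peak_set.chroms()])
    report.peaks_bad_chrom = int((~chrom_ok).sum())
    m = matrix.subset(peak_mask=chrom_ok) if not chrom_ok.all() else matrix

    while True:
        cell_ok = m.peaks_per_cell() >= min_peaks_per_cell
        if not cell_ok.any():
            raise EmptyMatrixError(
                f"empty after QC: no cell of type {m.cell_type!r} has "
                f">= {min_peaks_per_cell} open peaks"
            )
        if not cell_ok.all():
            report.cells_low_peaks += int((~cell_ok).sum())
            m = m.subset(cell_mask=cell_ok)
        peak_ok = m.cells_per_peak() > 0
        if not peak_ok.any():
            raise EmptyMatrixError(f"empty after QC: no peak with signal ({m.cell_type!r})")
        if not peak_ok.all():
            report.peaks_zero_signal += int((~peak_ok).sum())
            m = m.subset(peak_mask=peak_ok)
        if cell_ok.all() and peak_ok.all():
            break
    return m, report


def split_by_cell_type(
    matrix: BinaryAccessibilityMatrix,
    metadata: pd.DataFrame,
    min_cells: int = 50,
) -> dict[str, BinaryAccessibilityMatrix]:
    """Split a mixed matrix into one matrix per cell type.

    ``metadata`` must map every barcode to a cell_type. Cell types with
    fewer than ``min_cells`` cells are dropped (and logged).
    """
    lut: Mapping[str, str] = dict(zip(metadata["barcode"], metadata["cell_type"]))
    missing = [bc for bc in matrix.cell_ids if bc not in lut]
    if missing:
        shown = ", ".join(missing[:10])
        raise ValueError(
            f"{len(missing)} barcodes missing from metadata: {shown}"
            + ("..." if len(missing) > 10 else "")
        )
    labels = np.array([lut[bc] for bc in matrix.cell_ids])
    out: dict[str, BinaryAccessibilityMatrix] = {}
    for ct in sorted(set(labels)):
        mask = labels == ct
        n = int(mask.sum())
        if n < min_cells:
            logger.info("dropping cell type %r with %d < %d cells", ct, n, min_cells)
            continue
        sub = matrix.subset(cell_mask=mask)
        sub.cell_type = ct
        out[ct] = sub
    return out
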