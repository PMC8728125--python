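"""Genomic interval model and on-disk formats.

All coordinates are 0-based half-open (BED convention). Strand is ignored
for peaks and overlap tests — chromatin accessibility is unstranded — and
honored only when locating gene TSSs and promoter windows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "GeneAnnotation",
    "RegionSet",
    "BedParseError",
    "overlaps",
    "read_bed",
    "read_gene_annotation",
    "read_barcodes",
    "read_matrix_triplet",
    "write_matrix_triplet",
    "write_bed",
    "write_enhancers_bed",
    "write_interactions_tsv",
    "parse_peak_name",
]


class BedParseError(ValueError):
    """Malformed interval file (bad coordinates, wrong field count)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``.

    Strand is one of ``+``, ``-`` or ``.`` (unspecified).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base pair."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


_PEAK_NAME_RE = re.compile(r"^(?P<chrom>.+?)[:_](?P<start>\d+)[-_](?P<end>\d+)$")


def parse_peak_name(name: str) -> GenomicInterval:
    """Parse ``chrom:start-end`` or ``chrom_start_end`` into an interval."""
    m = _PEAK_NAME_RE.match(name.strip())
    if m is None:
        raise BedParseError(f"cannot parse peak name {name!r}")
    return GenomicInterval(m["chrom"], int(m["start"]), int(m["end"]))


class PeakSet:
    """Ordered, uniquely identified set of peaks (the matrix row space).

    Peaks are stored sorted by (chrom, start, end); ids default to
    ``chrom:start-end``.
    """

    def __init__(
        self,
        peaks: Sequence[GenomicInterval],
        ids: Sequence[str] | None = None,
    ) -> None:
        peaks = list(peaks)
        if ids is None:
            ids = [p.name for p in peaks]
        ids = list(ids)
        if len(ids) != len(peaks):
            raise ValueError("ids and peaks must have equal length")
        if len(set(ids)) != len(ids):
            raise ValueError("peak ids must be unique")
        order = sorted(range(len(peaks)), key=lambda i: (peaks[i].chrom, peaks[i].start, peaks[i].end))
        self.peaks: list[GenomicInterval] = [peaks[i] for i in order]
        self.ids: list[str] = [ids[i] for i in order]
        self._sort_order = np.asarray(order, dtype=np.intp)
        self._id_index = {pid: i for i, pid in enumerate(self.ids)}

    @property
    def sort_order(self) -> np.ndarray:
        """Permutation mapping original input order to stored sorted order."""
        return self._sort_order

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.peaks[i]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PeakSet)
            and self.peaks == other.peaks
            and self.ids == other.ids
        )

    def index_of(self, peak_id: str) -> int:
        return self._id_index[peak_id]

    def subset(self, mask_or_indices) -> "PeakSet":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return PeakSet([self.peaks[i] for i in idx], [self.ids[i] for i in idx])

    def starts(self) -> np.ndarray:
        return np.fromiter((p.start for p in self.peaks), dtype=np.int64, count=len(self))

    def ends(self) -> np.ndarray:
        return np.fromiter((p.end for p in self.peaks), dtype=np.int64, count=len(self))

    def chroms(self) -> list[str]:
        return [p.chrom for p in self.peaks]

    def midpoints(self) -> np.ndarray:
        return np.fromiter((p.midpoint for p in self.peaks), dtype=np.int64, count=len(self))


@dataclass
class GeneAnnotation:
    """One gene: TSS location plus exon intervals (all on one chromosome)."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    exons: list[GenomicInterval] = field(default_factory=list)
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        for e in self.exons:
            if e.chrom != self.chrom:
                raise ValueError(
                    f"exon chrom {e.chrom} differs from gene chrom {self.chrom}"
                )

    def promoter(self, upstream: int = 1000, downstream: int = 100) -> GenomicInterval:
        """Strand-aware promoter window around the TSS, half-open."""
        if self.strand == "+":
            start, end = self.tss - upstream, self.tss + downstream
        else:
            start, end = self.tss - downstream, self.tss + upstream
        return GenomicInterval(self.chrom, max(0, start), max(1, end))


@dataclass
class RegionSet:
    """Named collection of intervals (silencers, gold standard, ...)."""

    name: str
    intervals: list[GenomicInterval]
    extra: list[tuple[str, ...]] | None = None  # trailing BED columns, opaque

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, name: str | None = None) -> RegionSet:
    """Read a BED file (>=3 tab-separated columns) into a sorted RegionSet.

    Extra columns beyond chrom/start/end are preserved verbatim as opaque
    annotations, aligned to the sorted interval order.
    """
    path = Path(path)
    records: list[tuple[GenomicInterval, tuple[str, ...]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            try:
                iv = GenomicInterval(fields[0], start, end)
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
            records.append((iv, tuple(fields[3:])))
    records.sort(key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    return RegionSet(
        name=name or path.stem,
        intervals=[r[0] for r in records],
        extra=[r[1] for r in records],
    )


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read the gene annotation TSV (one exon per line).

    Columns: gene_id, chrom, strand, tss, exon_start, exon_end. A header
    line is detected and skipped.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["gene_id", "chrom", "strand", "tss", "exon_start", "exon_end"],
        dtype=str,
        comment="#",
    )
    if len(df) and df.iloc[0]["gene_id"] == "gene_id":
        df = df.iloc[1:]
    genes: dict[str, GeneAnnotation] = {}
    for row in df.itertuples(index=False):
        gid = row.gene_id
        if gid not in genes:
            genes[gid] = GeneAnnotation(
                gene_id=gid,
                chrom=row.chrom,
                strand=row.strand,
                tss=int(row.tss),
            )
        g = genes[gid]
        exon = GenomicInterval(row.chrom, int(row.exon_start), int(row.exon_end))
        if exon.chrom != g.chrom:
            raise ValueError(f"gene {gid}: exon on {exon.chrom}, gene on {g.chrom}")
        g.exons.append(exon)
    return list(genes.values())


def read_barcodes(path: str | Path) -> pd.DataFrame:
    """Read barcode metadata TSV with columns barcode, cell_type, dataset_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"barcode", "cell_type", "dataset_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"barcode file missing columns: {sorted(missing)}")
    if df["barcode"].duplicated().any():
        raise ValueError("duplicate barcodes in metadata")
    return df


def read_matrix_triplet(
    matrix_path: str | Path,
    peaks_path: str | Path,
    barcodes_path: str | Path,
) -> tuple[sp.csr_matrix, PeakSet, pd.DataFrame]:
    """Read a Matrix Market triplet plus its peak BED and barcode TSV sidecars.

    Matrix rows correspond to peaks, columns to barcodes. The returned
    matrix rows are permuted into the PeakSet's sorted order so row i always
    matches ``peak_set[i]``.
    """
    counts = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    file_regions = _read_bed_file_order(peaks_path)
    barcodes = read_barcodes(barcodes_path)
    if counts.shape[0] != len(file_regions):
        raise ValueError(
            f"matrix has {counts.shape[0]} rows but peak file has "
            f"{len(file_regions)} intervals"
        )
    if counts.shape[1] != len(barcodes):
        raise ValueError(
            f"matrix has {counts.shape[1]} columns but barcode file has "
            f"{len(barcodes)} entries"
        )
    if counts.nnz and counts.data.min() < 0:
        raise ValueError("negative count entry in matrix")
    peak_set = PeakSet(file_regions)
    # PeakSet sorts; permute matrix rows so row i matches peak_set[i].
    counts = sp.csr_matrix(counts[peak_set.sort_order])
    return counts, peak_set, barcodes


def _read_bed_file_order(path: str | Path) -> list[GenomicInterval]:
    """Read BED intervals preserving file order (no sorting)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 fields")
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


# ---------------------------------------------------------------------------
# Writers (deterministic byte-for-byte given identical inputs)
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def write_enhancers_bed(calls, path: str | Path) -> None:
    """Write enhancer calls as BED with id and fixed-precision score columns."""
    with open(path, "w") as fh:
        for call in calls:
            iv = call.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{call.peak_id}\t{call.score:.6f}\n")


def write_interactions_tsv(interactions, path: str | Path) -> None:
    """Write enhancer-gene interactions as TSV with a header line."""
    with open(path, "w") as fh:
        fh.write(
            "enhancer_chrom\tenhancer_start\tenhancer_end\tgene_id\t"
            "promoter_chrom\tpromoter_start\tpromoter_end\tscore\n"
        )
        for rec in interactions:
            e, p = rec.enhancer, rec.promoter_peak
            fh.write(
                f"{e.chrom}\t{e.start}\t{e.end}\t{rec.gene_id}\t"
                f"{p.chrom}\t{p.start}\t{p.end}\t{rec.score:.6f}\n"
            )


def write_matrix_triplet(
    counts: sp.spmatrix,
    peak_set: PeakSet,
    barcodes: pd.DataFrame,
    matrix_path: str | Path,
    peaks_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    """Write the (matrix, peaks, barcodes) triplet in the pipeline's input formats."""
    coo = sp.coo_matrix(counts)
    order = np.lexsort((coo.row, coo.col))
    with open(matrix_path, "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{coo.shape[0]} {coo.shape[1]} {coo.nnz}\n")
        for r, c, v in zip(coo.row[order], coo.col[order], coo.data[order]):
            fh.write(f"{r + 1} {c + 1} {int(v)}\n")
    write_bed(peak_set.peaks, peaks_path)
    barcodes.to_csv(barcodes_path, sep="\t", index=False)
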