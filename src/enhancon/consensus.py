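"""Jaccard-weighted consensus peak scoring, shuffle null, and enhancer calls.

The integration model treats each single cell of a cell type as one noisy
vote on which peaks are open. A cell that agrees with the other cells of
its type (high mean Jaccard similarity) is considered high-quality and
receives a larger weight; the consensus score of a peak is the weighted
fraction of cells open there. Candidate enhancers must beat a
shuffle-based signal null, avoid promoter/exon/silencer regions, and show
co-accessibility with at least one gene promoter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree

from .intervals import GeneAnnotation, GenomicInterval, PeakSet, RegionSet
from .matrix import BinaryAccessibilityMatrix

__all__ = [
    "JaccardMatrix",
    "CellWeights",
    "ConsensusScores",
    "EnhancerCall",
    "jaccard",
    "jaccard_matrix",
    "cell_weights",
    "consensus_scores",
    "shuffle_null",
    "region_filters",
    "call_enhancers",
    "celltype_similarity",
    "score_table",
]

logger = logging.getLogger(__name__)


@dataclass
class JaccardMatrix:
    """Symmetric n_cells x n_cells matrix of pairwise Jaccard coefficients."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.cell_ids):
            raise ValueError("Jaccard matrix must be square and match cell_ids")


@dataclass
class CellWeights:
    """Per-cell quality weights derived from the Jaccard matrix; sum to 1."""

    weights: np.ndarray
    cell_ids: list[str]


@dataclass
class ConsensusScores:
    """Weighted consensus signal per peak, in [0, 1]."""

    scores: np.ndarray
    peak_ids: list[str]
    null_threshold: float | None = None


@dataclass
class EnhancerCall:
    """A peak passing all enhancer filters, with its consensus score."""

    interval: GenomicInterval
    peak_id: str
    score: float
    passed_null: bool
    has_promoter_connection: bool
    best_connection_score: float


def jaccard(ci: np.ndarray, cj: np.ndarray) -> float:
    """Jaccard coefficient |Ci ∩ Cj| / |Ci ∪ Cj| of two binary vectors."""
    ci = np.asarray(ci).ravel().astype(bool)
    cj = np.asarray(cj).ravel().astype(bool)
    if ci.shape != cj.shape:
        raise ValueError("vectors must have equal length")
    union = int(np.logical_or(ci, cj).sum())
    if union == 0:
        raise ValueError("Jaccard undefined: both cells have no open peaks")
    inter = int(np.logical_and(ci, cj).sum())
    return inter / union


def jaccard_matrix(matrix: BinaryAccessibilityMatrix) -> JaccardMatrix:
    """Exact pairwise Jaccard matrix via sparse intersection counts."""
    X = sp.csc_matrix(matrix.values, dtype=np.int64)
    sizes = np.asarray(X.sum(axis=0)).ravel()
    if (sizes == 0).any():
        bad = int(np.flatnonzero(sizes == 0)[0])
        raise ValueError(f"cell {matrix.cell_ids[bad]!r} has no open peaks (run QC first)")
    inter = np.asarray((X.T @ X).todense(), dtype=np.float64)
    union = sizes[:, None] + sizes[None, :] - inter
    J = inter / union
    np.fill_diagonal(J, 1.0)
    return JaccardMatrix(values=J, cell_ids=list(matrix.cell_ids))


def cell_weights(J: JaccardMatrix) -> CellWeights:
    """Quality weight of each cell from the Jaccard matrix.

    w_i = sum_{j != i} J(i, j) / sum_{j != k} J(j, k), where the denominator
    runs over all ordered pairs, so the weights sum to exactly 1.
    """
    V = J.values
    n = V.shape[0]
    if n < 2:
        raise ValueError("weights undefined for a single cell")
    numer = V.sum(axis=1) - np.diag(V)
    denom = V.sum() - np.trace(V)
    if denom == 0:
        warnings.warn(
            "all off-diagonal Jaccard coefficients are zero; using uniform weights",
            RuntimeWarning,
            stacklevel=2,
        )
        w = np.full(n, 1.0 / n)
    else:
        w = numer / denom
    return CellWeights(weights=w, cell_ids=list(J.cell_ids))


def consensus_scores(
    matrix: BinaryAccessibilityMatrix, weights: CellWeights
) -> ConsensusScores:
    """Per-peak weighted consensus signal: S(i) = sum_j w_j * S_j(i)."""
    w = np.asarray(weights.weights, dtype=np.float64)
    if w.shape[0] != matrix.n_cells:
        raise ValueError(
            f"{w.shape[0]} weights for {matrix.n_cells} cells"
        )
    scores = matrix.values @ w
    scores = np.clip(np.asarray(scores).ravel(), 0.0, 1.0)
    return ConsensusScores(scores=scores, peak_ids=list(matrix.peak_set.ids))


def shuffle_null(
    matrix: BinaryAccessibilityMatrix,
    weights: CellWeights,
    n_shuffles: int = 100,
    percentile: float = 95.0,
    seed: int | None = None,
) -> float:
    """Signal-null threshold from per-cell peak shuffling.

    Each shuffle reassigns every cell's open peaks to uniformly random peak
    positions (preserving that cell's open-peak count) and recomputes the
    weighted consensus scores. All shuffled per-peak scores are pooled into
    one null distribution; the stated percentile of that pool is returned.
    A peak passes the null iff its observed score is strictly greater.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if not (0.0 < percentile < 100.0):
        raise ValueError("percentile must be in (0, 100)")
    rng = np.random.default_rng(seed)
    w = np.asarray(weights.weights, dtype=np.float64)
    n_peaks = matrix.n_peaks
    opens = matrix.peaks_per_cell()
    null = np.empty((n_shuffles, n_peaks), dtype=np.float64)
    for s in range(n_shuffles):
        acc = np.zeros(n_peaks)
        for j, m in enumerate(opens):
            idx = rng.permutation(n_peaks)[:m]
            acc[idx] += w[j]
        null[s] = acc
    return float(np.percentile(null.ravel(), percentile))


def _exclusion_trees(
    genes: Sequence[GeneAnnotation],
    silencers: RegionSet | None,
    promoter_window: tuple[int, int],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}

    def add(iv: GenomicInterval) -> None:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    up, down = promoter_window
    for g in genes:
        add(g.promoter(up, down))
        for e in g.exons:
            add(e)
    if silencers is not None:
        for iv in silencers:
            add(iv)
    return trees


def region_filters(
    peak_set: PeakSet,
    genes: Sequence[GeneAnnotation],
    silencers: RegionSet | None = None,
    promoter_window: tuple[int, int] = (1000, 100),
) -> np.ndarray:
    """Boolean mask: True for peaks clear of promoters, exons, and silencers.

    A peak is excluded if it shares >= 1 bp with any exon, any strand-aware
    promoter window (TSS - upstream .. TSS + downstream), or any silencer.
    """
    if not genes:
        raise ValueError("gene annotation must be non-empty")
    trees = _exclusion_trees(genes, silencers, promoter_window)
    mask = np.ones(len(peak_set), dtype=bool)
    for i, p in enumerate(peak_set):
        tree = trees.get(p.chrom)
        if tree is not None and tree.overlap(p.start, p.end):
            mask[i] = False
    return mask


def call_enhancers(
    scores: ConsensusScores,
    null_mask: np.ndarray,
    region_mask: np.ndarray,
    connection_mask: np.ndarray,
    peak_set: PeakSet,
    best_connection_scores: np.ndarray | None = None,
) -> list[EnhancerCall]:
    """Emit enhancer calls for peaks passing all three filters."""
    n = len(peak_set)
    for name, m in (
        ("null_mask", null_mask),
        ("region_mask", region_mask),
        ("connection_mask", connection_mask),
    ):
        if len(m) != n:
            raise ValueError(f"{name} has length {len(m)}, expected {n}")
    if best_connection_scores is None:
        best_connection_scores = np.where(connection_mask, np.nan, 0.0)
    calls = []
    for i in np.flatnonzero(
        np.asarray(null_mask, bool)
        & np.asarray(region_mask, bool)
        & np.asarray(connection_mask, bool)
    ):
        calls.append(
            EnhancerCall(
                interval=peak_set[i],
                peak_id=peak_set.ids[i],
                score=float(scores.scores[i]),
                passed_null=True,
                has_promoter_connection=True,
                best_connection_score=float(best_connection_scores[i]),
            )
        )
    return calls


def _merged_bp(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """Merge intervals per chromosome into disjoint (start, end) arrays."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged = []
        cs, ce = ivs[0]
        for s, e in ivs[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                merged.append((cs, ce))
                cs, ce = s, e
        merged.append((cs, ce))
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


def _bp_jaccard(a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]) -> float:
    if not a and not b:
        return 0.0
    if not a or not b:
        return 0.0
    ma, mb = _merged_bp(a), _merged_bp(b)
    inter = 0
    for chrom in set(ma) & set(mb):
        ia, ib = ma[chrom], mb[chrom]
        # two-pointer sweep over disjoint sorted intervals
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i, 0], ib[j, 0])
            e = min(ia[i, 1], ib[j, 1])
            if e > s:
                inter += e - s
            if ia[i, 1] <= ib[j, 1]:
                i += 1
            else:
                j += 1
    size = lambda m: sum(int((arr[:, 1] - arr[:, 0]).sum()) for arr in m.values())
    union = size(ma) + size(mb) - inter
    return inter / union if union else 0.0


def celltype_similarity(
    call_sets: Mapping[str, Sequence[GenomicInterval]]
) -> pd.DataFrame:
    """Base-pair Jaccard similarity between cell types' enhancer sets."""
    if len(call_sets) < 2:
        raise ValueError("need at least two cell types")
    names = sorted(call_sets)
    n = len(names)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = _bp_jaccard(
                list(call_sets[names[i]]), list(call_sets[names[j]])
            )
    return pd.DataFrame(M, index=names, columns=names)


def score_table(
    scores: ConsensusScores,
    null_mask: np.ndarray,
    region_mask: np.ndarray,
    connection_mask: np.ndarray,
) -> pd.DataFrame:
    """Per-peak audit table: score plus pass/fail for each filter."""
    return pd.DataFrame(
        {
            "peak_id": scores.peak_ids,
            "consensus_score": scores.scores,
            "pass_null": np.asarray(null_mask, bool),
            "pass_region": np.asarray(region_mask, bool),
            "pass_connection": np.asarray(connection_mask, bool),
        }
    )
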