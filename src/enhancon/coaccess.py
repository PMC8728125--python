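"""Co-accessibility between peaks: TF-IDF/LSI, metacells, graphical lasso.

Binary scATAC matrices are far too sparse for direct covariance
estimation, so the matrix is TF-IDF normalized, embedded by truncated SVD
(latent semantic indexing), and similar cells are summed into metacells to
densify counts. Co-accessibility between peaks within a genomic distance
window is then the (negated, rescaled) partial correlation from a sparse
inverse-covariance estimate, where the graphical-lasso penalty on each
peak pair grows with their base-pair distance — distal pairs need stronger
evidence. Distal peaks linked to a gene-promoter peak above a score cutoff
become enhancer–gene interactions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree
from numba import njit

from .intervals import GeneAnnotation, GenomicInterval, PeakSet
from .matrix import BinaryAccessibilityMatrix

__all__ = [
    "TfIdfMatrix",
    "ReducedEmbedding",
    "AggregatedMatrix",
    "CoaccessibilityPair",
    "EnhancerGeneInteraction",
    "tfidf_transform",
    "lsi_embed",
    "embed_2d",
    "aggregate_cells",
    "penalized_graphical_lasso",
    "coaccessibility_scores",
    "promoter_peak_mask",
    "connection_mask_and_interactions",
    "pairs_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class TfIdfMatrix:
    """TF-IDF reweighted peaks x cells matrix plus the per-peak IDF vector."""

    values: sp.csr_matrix
    idf: np.ndarray
    peak_ids: list[str]
    cell_ids: list[str]


@dataclass
class ReducedEmbedding:
    """LSI cell embedding: right-singular vectors scaled by singular values.

    ``coordinates`` is cells x d. ``loadings`` (peaks x d) retains the left
    singular vectors so the factorization can be checked or reused.
    """

    coordinates: np.ndarray
    singular_values: np.ndarray
    loadings: np.ndarray
    cell_ids: list[str]
    dropped_first: bool = True


@dataclass
class AggregatedMatrix:
    """Peaks x metacells summed binary counts with metacell membership."""

    values: np.ndarray
    membership: list[np.ndarray]
    peak_ids: list[str]
    k: int


@dataclass(frozen=True)
class CoaccessibilityPair:
    """Symmetric co-accessibility score between two peaks."""

    peak_i: str
    peak_j: str
    score: float
    distance: int


@dataclass(frozen=True)
class EnhancerGeneInteraction:
    """A distal peak linked to a gene through a promoter peak."""

    enhancer: GenomicInterval
    gene_id: str
    promoter_peak: GenomicInterval
    score: float


# ---------------------------------------------------------------------------
# TF-IDF / LSI
# ---------------------------------------------------------------------------

def tfidf_transform(matrix: BinaryAccessibilityMatrix) -> TfIdfMatrix:
    """TF-IDF normalization of a binary matrix M.

    TF divides each cell's column by its column sum; the per-peak IDF is
    log(1 + n_cells / rowSums(M)) (natural log); the output multiplies each
    TF row by its IDF entry.
    """
    M = sp.csc_matrix(matrix.values, dtype=np.float64)
    colsums = np.asarray(M.sum(axis=0)).ravel()
    rowsums = np.asarray(M.sum(axis=1)).ravel()
    if (colsums == 0).any():
        j = int(np.flatnonzero(colsums == 0)[0])
        raise ValueError(f"column {j} ({matrix.cell_ids[j]!r}) has zero sum")
    if (rowsums == 0).any():
        i = int(np.flatnonzero(rowsums == 0)[0])
        raise ValueError(f"row {i} ({matrix.peak_set.ids[i]!r}) has zero sum")
    tf = M @ sp.diags(1.0 / colsums)
    idf = np.log(1.0 + matrix.n_cells / rowsums)
    values = sp.csr_matrix(sp.diags(idf) @ tf)
    return TfIdfMatrix(
        values=values,
        idf=idf,
        peak_ids=list(matrix.peak_set.ids),
        cell_ids=list(matrix.cell_ids),
    )


def lsi_embed(
    tfidf: TfIdfMatrix, n_components: int = 50, drop_first: bool = True
) -> ReducedEmbedding:
    """Truncated SVD of the TF-IDF matrix (latent semantic indexing).

    The first component tracks per-cell read depth and is dropped by
    default, keeping components 2..n_components. Cell coordinates are the
    right singular vectors scaled by their singular values. Signs are fixed
    so each component's largest-magnitude peak loading is positive.

    Uses a dense LAPACK SVD: deterministic, and the matrices handled here
    (at most a few thousand cells) are well within dense range.
    """
    if n_components < 2:
        raise ValueError("n_components must be >= 2")
    A = np.asarray(tfidf.values.todense(), dtype=np.float64)
    k_max = min(A.shape)
    if n_components > k_max:
        warnings.warn(
            f"n_components={n_components} clipped to min(shape)={k_max}",
            RuntimeWarning,
            stacklevel=2,
        )
        n_components = k_max
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    U, s, Vt = U[:, :n_components], s[:n_components], Vt[:n_components]
    # deterministic sign convention
    for c in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, c])))
        if U[i, c] < 0:
            U[:, c] = -U[:, c]
            Vt[c] = -Vt[c]
    start = 1 if drop_first else 0
    coords = (Vt.T * s)[:, start:]
    return ReducedEmbedding(
        coordinates=coords,
        singular_values=s[start:],
        loadings=U[:, start:],
        cell_ids=list(tfidf.cell_ids),
        dropped_first=drop_first,
    )


def embed_2d(
    embedding: ReducedEmbedding,
    seed: int,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """Seeded 2-D UMAP of the LSI coordinates, for visualization."""
    n = embedding.coordinates.shape[0]
    if n < 2:
        raise ValueError("need at least two cells to embed")
    import umap  # heavy import, keep local

    n_neighbors = min(n_neighbors, n - 1)
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(embedding.coordinates))


# ---------------------------------------------------------------------------
# Metacell aggregation
# ---------------------------------------------------------------------------

def aggregate_cells(
    matrix: BinaryAccessibilityMatrix,
    embedding: ReducedEmbedding,
    k: int = 50,
    seed: int | None = None,
    max_metacells: int | None = None,
) -> AggregatedMatrix:
    """Sum k-nearest-neighbor groups of cells into metacells.

    Seed cells are drawn without replacement in random order; each seed
    that is not yet covered spawns a metacell of its k nearest neighbors
    (itself included) in embedding space. Sampling stops once every cell
    belongs to at least one metacell or ``max_metacells`` is reached.
    """
    from sklearn.neighbors import NearestNeighbors

    n = matrix.n_cells
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells {n}")
    if embedding.coordinates.shape[0] != n:
        raise ValueError("embedding does not match matrix cells")
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k).fit(embedding.coordinates)
    _, neigh = nn.kneighbors(embedding.coordinates)
    covered = np.zeros(n, dtype=bool)
    membership: list[np.ndarray] = []
    for cand in rng.permutation(n):
        if covered.all():
            break
        if covered[cand]:
            continue
        members = np.sort(neigh[cand])
        membership.append(members)
        covered[members] = True
        if max_metacells is not None and len(membership) >= max_metacells:
            break
    X = sp.csc_matrix(matrix.values)
    values = np.column_stack(
        [np.asarray(X[:, m].sum(axis=1)).ravel() for m in membership]
    ).astype(np.int64)
    return AggregatedMatrix(
        values=values,
        membership=membership,
        peak_ids=list(matrix.peak_set.ids),
        k=k,
    )


# ---------------------------------------------------------------------------
# Graphical lasso with elementwise penalty matrix
# ---------------------------------------------------------------------------

@njit(cache=True)
def _glasso_core(S, rho, max_iter, tol, cd_max_iter, cd_tol):  # pragma: no cover
    p = S.shape[0]
    W = S.copy()
    for i in range(p):
        W[i, i] = S[i, i] + rho[i, i]
    B = np.zeros((p, p))
    # convergence threshold scaled by mean absolute off-diagonal of S
    mean_off = 0.0
    if p > 1:
        for i in range(p):
            for j in range(p):
                if i != j:
                    mean_off += abs(S[i, j])
        mean_off /= p * (p - 1)
    if mean_off <= 0.0:
        mean_off = 1.0
    w_new = np.empty(p)
    converged = False
    for _ in range(max_iter):
        max_dw = 0.0
        for j in range(p):
            beta = B[:, j].copy()
            beta[j] = 0.0
            for _ in range(cd_max_iter):
                max_db = 0.0
                for i in range(p):
                    if i == j:
                        continue
                    r = S[i, j] - (np.dot(W[i], beta) - W[i, i] * beta[i])
                    t = rho[i, j]
                    if r > t:
                        b = (r - t) / W[i, i]
                    elif r < -t:
                        b = (r + t) / W[i, i]
                    else:
                        b = 0.0
                    d = abs(b - beta[i])
                    if d > max_db:
                        max_db = d
                    beta[i] = b
                if max_db < cd_tol:
                    break
            B[:, j] = beta
            for i in range(p):
                if i == j:
                    continue
                w_new[i] = np.dot(W[i], beta)
            for i in range(p):
                if i == j:
                    continue
                d = abs(w_new[i] - W[i, j])
                if d > max_dw:
                    max_dw = d
                W[i, j] = w_new[i]
                W[j, i] = w_new[i]
        if max_dw < tol * mean_off:
            converged = True
            break
    Theta = np.zeros((p, p))
    for j in range(p):
        dot = 0.0
        for i in range(p):
            if i != j:
                dot += W[i, j] * B[i, j]
        denom = W[j, j] - dot
        if denom <= 0.0:
            denom = 1e-12
        t22 = 1.0 / denom
        Theta[j, j] = t22
        for i in range(p):
            if i != j:
                Theta[i, j] = -B[i, j] * t22
    # symmetrize
    for i in range(p):
        for j in range(i + 1, p):
            v = 0.5 * (Theta[i, j] + Theta[j, i])
            Theta[i, j] = v
            Theta[j, i] = v
    return W, Theta, converged


def penalized_graphical_lasso(
    S: np.ndarray,
    rho: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-4,
    cd_max_iter: int = 200,
    cd_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Sparse inverse covariance with an elementwise L1 penalty matrix.

    Minimizes  -log det(Theta) + tr(S Theta) + sum_ij rho_ij |Theta_ij|
    by block coordinate descent on the covariance estimate (each column
    update is a lasso regression solved by coordinate descent).

    Returns (covariance estimate W, precision estimate Theta, converged).
    """
    S = np.ascontiguousarray(S, dtype=np.float64)
    rho = np.ascontiguousarray(rho, dtype=np.float64)
    if S.shape != rho.shape or S.shape[0] != S.shape[1]:
        raise ValueError("S and rho must be square matrices of equal shape")
    if S.shape[0] == 1:
        W = S + rho
        return W, 1.0 / W, True
    return _glasso_core(S, rho, max_iter, tol, cd_max_iter, cd_tol)


def _precision_to_partial_corr(Theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.clip(np.diag(Theta), 1e-12, None))
    P = -Theta / np.outer(d, d)
    np.fill_diagonal(P, 1.0)
    return np.clip(P, -1.0, 1.0)


def coaccessibility_scores(
    agg: AggregatedMatrix,
    peak_set: PeakSet,
    window_bp: int = 500_000,
    penalty_base: float = 0.4,
    distance_penalty_scale: float = 0.25,
    min_open_frac: float = 0.05,
    diag_regularization: float = 1e-3,
    max_iter: int = 100,
) -> list[CoaccessibilityPair]:
    """Distance-limited co-accessibility scores between peaks.

    The genome is tiled into overlapping windows of ``window_bp`` (50%
    overlap). Within each window, metacell counts are z-scored per peak and
    a graphical lasso is fit to their correlation matrix with off-diagonal
    penalty ``penalty_base + distance_penalty_scale * distance /
    window_bp``: the constant floor soft-thresholds away sampling noise in
    the correlation estimates (metacells are few and share member cells),
    and the distance term penalizes distant pairs more. The score of a
    pair is the negated rescaled partial correlation from the precision
    estimate, clamped to [-1, 1]; pairs seen in several windows get the
    mean.

    Peaks with zero variance, or whose mean aggregated count is below
    ``min_open_frac * k`` (open in fewer than ~min_open_frac of cells),
    are dropped from estimation and produce no pairs: at that sparsity an
    aggregated count vector is essentially an indicator of the few open
    cells' metacell membership, which manufactures spurious correlations
    between unrelated rare peaks.
    """
    if agg.values.shape[1] < 2:
        raise ValueError("need at least two metacells")
    if list(agg.peak_ids) != list(peak_set.ids):
        raise ValueError("aggregated matrix peaks do not match peak set")
    X = agg.values.astype(np.float64)
    sd = X.std(axis=1)
    usable = (sd > 0) & (X.mean(axis=1) >= min_open_frac * agg.k)
    mids = peak_set.midpoints()
    chroms = np.asarray(peak_set.chroms())

    acc: dict[tuple[str, str], list[float]] = {}
    dist_of: dict[tuple[str, str], int] = {}
    step = window_bp // 2
    for chrom in sorted(set(chroms)):
        on_chrom = np.flatnonzero((chroms == chrom) & usable)
        if len(on_chrom) < 2:
            continue
        cmids = mids[on_chrom]
        lo = (int(cmids.min()) // step) * step - step
        hi = int(cmids.max())
        for wstart in range(max(lo, -step), hi + 1, step):
            wmask = (cmids >= wstart) & (cmids < wstart + window_bp)
            idx = on_chrom[wmask]
            if len(idx) < 2:
                continue
            Z = X[idx]
            Z = (Z - Z.mean(axis=1, keepdims=True)) / Z.std(axis=1, keepdims=True)
            S = (Z @ Z.T) / Z.shape[1]
            S[np.diag_indices_from(S)] += diag_regularization
            pm = mids[idx].astype(np.float64)
            dist = np.abs(pm[:, None] - pm[None, :])
            rho = penalty_base + distance_penalty_scale * dist / window_bp
            np.fill_diagonal(rho, 0.0)
            _, Theta, converged = penalized_graphical_lasso(
                S, rho, max_iter=max_iter
            )
            if not np.isfinite(Theta).all():
                logger.warning(
                    "skipping window %s:%d-%d: non-finite precision estimate",
                    chrom, wstart, wstart + window_bp,
                )
                continue
            if not converged:
                logger.warning(
                    "window %s:%d-%d: graphical lasso hit max_iter",
                    chrom, wstart, wstart + window_bp,
                )
            P = _precision_to_partial_corr(Theta)
            ids = [peak_set.ids[i] for i in idx]
            for a in range(len(idx)):
                for b in range(a + 1, len(idx)):
                    key = (ids[a], ids[b])
                    acc.setdefault(key, []).append(float(P[a, b]))
                    dist_of[key] = int(dist[a, b])
    return [
        CoaccessibilityPair(
            peak_i=i, peak_j=j, score=float(np.mean(v)), distance=dist_of[(i, j)]
        )
        for (i, j), v in sorted(acc.items())
    ]


def pairs_to_frame(pairs: Sequence[CoaccessibilityPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.peak_i, p.peak_j, p.score, p.distance) for p in pairs],
        columns=["peak_i", "peak_j", "score", "distance"],
    )


# ---------------------------------------------------------------------------
# Promoter peaks and enhancer-gene interactions
# ---------------------------------------------------------------------------

def promoter_peak_mask(
    peak_set: PeakSet,
    genes: Sequence[GeneAnnotation],
    promoter_window: tuple[int, int] = (1000, 100),
) -> tuple[np.ndarray, dict[int, set[str]]]:
    """Mark peaks overlapping >= 1 gene's promoter window.

    Returns the boolean mask and a map from peak index to the gene ids
    whose promoters it overlaps (multi-gene overlaps map to all genes).
    """
    if not genes:
        raise ValueError("gene annotation must be non-empty")
    up, down = promoter_window
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        pr = g.promoter(up, down)
        trees.setdefault(pr.chrom, IntervalTree()).addi(pr.start, pr.end, g.gene_id)
    mask = np.zeros(len(peak_set), dtype=bool)
    peak_genes: dict[int, set[str]] = {}
    for i, p in enumerate(peak_set):
        tree = trees.get(p.chrom)
        if tree is None:
            continue
        hits = tree.overlap(p.start, p.end)
        if hits:
            mask[i] = True
            peak_genes[i] = {h.data for h in hits}
    return mask, peak_genes


def connection_mask_and_interactions(
    pairs: Sequence[CoaccessibilityPair],
    promoter_mask: np.ndarray,
    peak_gene_map: Mapping[int, set[str]],
    peak_set: PeakSet,
    cutoff: float = 0.1,
) -> tuple[np.ndarray, list[EnhancerGeneInteraction]]:
    """Connection filter: distal peaks co-accessible with a gene promoter.

    A non-promoter peak passes iff some pair links it to a promoter peak
    with score >= cutoff. Each qualifying (peak, gene) becomes one
    interaction carrying the maximum score over that gene's promoter peaks.

    Returns (mask, interactions, best_connection_score_per_peak).
    """
    promoter_mask = np.asarray(promoter_mask, dtype=bool)
    mask = np.zeros(len(peak_set), dtype=bool)
    best: dict[tuple[int, str], tuple[float, int]] = {}
    best_conn = np.zeros(len(peak_set), dtype=np.float64)
    for pair in pairs:
        if pair.score < cutoff:
            continue
        i = peak_set.index_of(pair.peak_i)
        j = peak_set.index_of(pair.peak_j)
        for distal, prom in ((i, j), (j, i)):
            if promoter_mask[distal] or not promoter_mask[prom]:
                continue
            mask[distal] = True
            best_conn[distal] = max(best_conn[distal], pair.score)
            for gene in peak_gene_map.get(prom, set()):
                key = (distal, gene)
                if key not in best or pair.score > best[key][0]:
                    best[key] = (pair.score, prom)
    interactions = [
        EnhancerGeneInteraction(
            enhancer=peak_set[distal],
            gene_id=gene,
            promoter_peak=peak_set[prom],
            score=score,
        )
        for (distal, gene), (score, prom) in sorted(best.items())
    ]
    return mask, interactions, best_conn
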