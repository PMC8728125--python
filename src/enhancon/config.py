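"""Pipeline configuration and end-to-end orchestration.

Stage order: read -> binarize -> merge -> QC -> split by cell type -> per
type {Jaccard -> weights -> consensus -> shuffle null; TF-IDF -> LSI ->
metacell aggregation -> co-accessibility -> promoter/connection masks} ->
call -> write. Every random stage consumes a sub-seed derived from the
single run seed and the stage name, so stages can be rerun in isolation
reproducibly, and the log records every effective parameter.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coaccess, consensus, matrix as mx
from .intervals import (
    GeneAnnotation,
    RegionSet,
    read_bed,
    read_gene_annotation,
    read_matrix_triplet,
    write_enhancers_bed,
    write_interactions_tsv,
)
from .matrix import DEFAULT_CHROM_PATTERN, BinaryAccessibilityMatrix

__all__ = ["DatasetPaths", "PipelineConfig", "PipelineResult", "run_pipeline", "derive_seed"]

logger = logging.getLogger(__name__)


def derive_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    return (int(base_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class DatasetPaths:
    matrix: Path
    peaks: Path
    barcodes: Path


@dataclass
class PipelineConfig:
    """All inputs, outputs, and thresholds of one pipeline run.

    Threshold defaults are the method's standard operating values:
    cells need >= 200 open peaks, cell types >= 50 cells, the shuffle null
    uses 100 shuffles at the 95th percentile, and a co-accessibility score
    of >= 0.1 to a promoter peak is required of every enhancer.
    """

    datasets: list[DatasetPaths]
    genes: Path
    outdir: Path
    seed: int
    silencers: Path | None = None
    min_peaks_per_cell: int = 200
    min_cells_per_type: int = 50
    min_dataset_peaks: int = 200
    merge_gap: int = 0
    null_percentile: float = 95.0
    n_shuffles: int = 100
    connection_cutoff: float = 0.1
    window_bp: int = 500_000
    penalty_base: float = 0.4
    distance_penalty_scale: float = 0.25
    min_open_frac: float = 0.05
    k_aggregate: int = 50
    n_components: int = 50
    promoter_upstream: int = 1000
    promoter_downstream: int = 100
    allowed_chrom_pattern: str = DEFAULT_CHROM_PATTERN

    def __post_init__(self) -> None:
        self.datasets = [
            d if isinstance(d, DatasetPaths) else DatasetPaths(*map(Path, d))
            for d in self.datasets
        ]
        self.genes = Path(self.genes)
        self.outdir = Path(self.outdir)
        if self.silencers is not None:
            self.silencers = Path(self.silencers)

    def log_effective(self) -> None:
        for f in dataclasses.fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))


@dataclass
class CellTypeResult:
    cell_type: str
    calls: list
    interactions: list
    scores: consensus.ConsensusScores
    null_threshold: float
    table: pd.DataFrame
    pairs: list


@dataclass
class PipelineResult:
    by_type: dict[str, CellTypeResult]
    qc_report: mx.QCReport
    outdir: Path


def _load_and_binarize(config: PipelineConfig) -> tuple[list[BinaryAccessibilityMatrix], pd.DataFrame]:
    mats, metas = [], []
    for d, paths in enumerate(config.datasets):
        counts, peak_set, barcodes = read_matrix_triplet(
            paths.matrix, paths.peaks, paths.barcodes
        )
        bam = mx.binarize(
            counts,
            peak_set,
            list(barcodes["barcode"]),
            cell_type="all",
            dataset_id=str(barcodes["dataset_id"].iloc[0]) if len(barcodes) else f"dataset{d}",
        )
        bam.dataset_of_cell = list(barcodes["dataset_id"])
        mats.append(bam)
        metas.append(barcodes)
    return mats, pd.concat(metas, ignore_index=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full consensus-enhancer pipeline; returns per-type results."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(config.outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("enhancon")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        config.log_effective()
        return _run(config)
    finally:
        root.removeHandler(handler)
        handler.close()


def _stage(name: str):
    logger.info("stage: %s", name)


def _run(config: PipelineConfig) -> PipelineResult:
    _stage("read + binarize")
    mats, meta = _load_and_binarize(config)

    _stage("merge datasets")
    merged = mx.merge_datasets(
        mats, merge_gap=config.merge_gap, min_dataset_peaks=config.min_dataset_peaks
    )
    # merge may suffix duplicated barcodes; labels follow cell order
    meta_merged = pd.DataFrame(
        {
            "barcode": merged.cell_ids,
            "cell_type": list(meta["cell_type"]),
            "dataset_id": merged.dataset_of_cell,
        }
    )

    _stage("quality control")
    merged, qc_report = mx.qc_filter(
        merged,
        min_peaks_per_cell=config.min_peaks_per_cell,
        allowed_chrom_pattern=config.allowed_chrom_pattern,
    )
    qc_report.to_frame().to_csv(config.outdir / "qc_report.tsv", sep="\t", index=False)

    _stage("split by cell type")
    by_type = mx.split_by_cell_type(
        merged, meta_merged, min_cells=config.min_cells_per_type
    )
    if not by_type:
        raise mx.EmptyMatrixError("no cell type with enough cells after QC")

    genes = read_gene_annotation(config.genes)
    silencers = read_bed(config.silencers, name="silencers") if config.silencers else None
    window = (config.promoter_upstream, config.promoter_downstream)

    results: dict[str, CellTypeResult] = {}
    for ct, bam in sorted(by_type.items()):
        # peaks with signal only in other cell types are zero rows here;
        # re-run QC so per-type matrices satisfy the matrix invariants
        bam, _ = mx.qc_filter(
            bam,
            min_peaks_per_cell=config.min_peaks_per_cell,
            allowed_chrom_pattern=config.allowed_chrom_pattern,
        )
        results[ct] = _run_cell_type(config, ct, bam, genes, silencers, window)

    return PipelineResult(by_type=results, qc_report=qc_report, outdir=config.outdir)


def _run_cell_type(
    config: PipelineConfig,
    ct: str,
    bam: BinaryAccessibilityMatrix,
    genes: list[GeneAnnotation],
    silencers: RegionSet | None,
    promoter_window: tuple[int, int],
) -> CellTypeResult:
    _stage(f"[{ct}] jaccard + weights + consensus")
    J = consensus.jaccard_matrix(bam)
    w = consensus.cell_weights(J)
    scores = consensus.consensus_scores(bam, w)

    _stage(f"[{ct}] shuffle null")
    thr = consensus.shuffle_null(
        bam,
        w,
        n_shuffles=config.n_shuffles,
        percentile=config.null_percentile,
        seed=derive_seed(config.seed, f"shuffle:{ct}"),
    )
    scores.null_threshold = thr
    null_mask = scores.scores > thr

    _stage(f"[{ct}] region filters")
    region_mask = consensus.region_filters(
        bam.peak_set, genes, silencers, promoter_window
    )

    _stage(f"[{ct}] tfidf + lsi + aggregation")
    tfidf = coaccess.tfidf_transform(bam)
    emb = coaccess.lsi_embed(tfidf, n_components=config.n_components)
    k = min(config.k_aggregate, bam.n_cells)
    agg = coaccess.aggregate_cells(
        bam, emb, k=k, seed=derive_seed(config.seed, f"aggregate:{ct}")
    )

    _stage(f"[{ct}] co-accessibility")
    pairs = coaccess.coaccessibility_scores(
        agg,
        bam.peak_set,
        window_bp=config.window_bp,
        penalty_base=config.penalty_base,
        distance_penalty_scale=config.distance_penalty_scale,
        min_open_frac=config.min_open_frac,
    )
    prom_mask, peak_genes = coaccess.promoter_peak_mask(
        bam.peak_set, genes, promoter_window
    )
    conn_mask, interactions, best_conn = coaccess.connection_mask_and_interactions(
        pairs, prom_mask, peak_genes, bam.peak_set, cutoff=config.connection_cutoff
    )

    _stage(f"[{ct}] call + write")
    calls = consensus.call_enhancers(
        scores, null_mask, region_mask, conn_mask, bam.peak_set, best_conn
    )
    table = consensus.score_table(scores, null_mask, region_mask, conn_mask)
    write_enhancers_bed(calls, config.outdir / f"enhancers_{ct}.bed")
    write_interactions_tsv(interactions, config.outdir / f"interactions_{ct}.tsv")
    table.to_csv(config.outdir / f"scores_{ct}.tsv", sep="\t", index=False)
    logger.info(
        "[%s] %d enhancer calls, %d interactions, null threshold %.6f",
        ct, len(calls), len(interactions), thr,
    )
    return CellTypeResult(
        cell_type=ct,
        calls=calls,
        interactions=interactions,
        scores=scores,
        null_threshold=thr,
        table=table,
        pairs=pairs,
    )
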