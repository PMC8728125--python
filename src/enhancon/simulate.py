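"""Seeded generator of scATAC-like binary fixtures with planted structure.

The generator emulates the statistical structure the consensus method
assumes: per cell type, a set of planted "true enhancer" peaks opens with
high probability while background peaks open rarely; planted
distal-peak/promoter-peak pairs co-open through a shared latent state
(tunable co-accessibility); and a per-cell depth multiplier scales all
open probabilities, mimicking sequencing-depth variation. Peaks are laid
out without overlap on one synthetic chromosome ("chrS") and synthetic
genes place a configurable fraction of peaks inside promoter windows.

Everything is reproducible from the config seed, and outputs are written
in exactly the pipeline's input formats (Matrix Market + BED + TSV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .intervals import (
    GeneAnnotation,
    GenomicInterval,
    PeakSet,
    write_bed,
    write_matrix_triplet,
)

__all__ = ["FixtureConfig", "FixtureTruth", "SimulatedFixture", "generate", "truth_eval"]


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic generator.

    Defaults define the standard benchmark configuration: two cell types
    of 200 cells over 1000 peaks, 20 planted enhancers per type opening at
    0.4 vs 0.02 background, and 20 co-accessible distal/promoter pairs
    co-opening with correlation 0.8.
    """

    n_cell_types: int = 2
    n_cells_per_type: int = 200
    n_peaks: int = 1000
    chrom_length: int = 3_000_000
    peak_width: int = 400
    n_planted_enhancers_per_type: int = 20
    p_open_enhancer: float = 0.4
    p_open_background: float = 0.02
    n_coaccessible_pairs: int = 20
    pair_correlation: float = 0.8
    p_open_pair: float = 0.3
    depth_multiplier_range: tuple[float, float] = (0.7, 1.3)
    promoter_fraction: float = 0.1
    pair_min_distance: int = 10_000
    pair_max_distance: int = 250_000
    chrom: str = "chrS"
    seed: int = 7

    def __post_init__(self) -> None:
        # equality permitted so null simulations (no planted signal) can be run
        if not (0.0 <= self.p_open_background <= self.p_open_enhancer <= 1.0):
            raise ValueError("require 0 <= p_open_background <= p_open_enhancer <= 1")
        for name in (
            "n_cell_types",
            "n_cells_per_type",
            "n_peaks",
            "chrom_length",
            "peak_width",
            "n_planted_enhancers_per_type",
            "n_coaccessible_pairs",
        ):
            if getattr(self, name) <= 0 and name != "n_coaccessible_pairs":
                raise ValueError(f"{name} must be positive")
        if self.n_peaks * self.peak_width > self.chrom_length:
            raise ValueError(
                f"{self.n_peaks} peaks of {self.peak_width} bp do not fit "
                f"in {self.chrom_length} bp"
            )
        lo, hi = self.depth_multiplier_range
        if not (0 < lo <= hi):
            raise ValueError("depth_multiplier_range must be 0 < lo <= hi")

    def expected_open_peaks_per_cell(self) -> float:
        """Expected open-peak count of a typical cell at mean depth."""
        n_prom = int(round(self.promoter_fraction * self.n_peaks))
        n_pair_peaks = 2 * self.n_coaccessible_pairs
        n_enh = self.n_planted_enhancers_per_type
        n_bg = self.n_peaks - n_enh - n_pair_peaks
        d = 0.5 * sum(self.depth_multiplier_range)
        return d * (
            self.p_open_background * n_bg
            + self.p_open_enhancer * n_enh
            + self.p_open_pair * n_pair_peaks
        )

    def suggested_min_peaks_per_cell(self) -> int:
        """QC depth threshold scaled to this simulation's depth.

        Half the expected open-peak count at the minimum depth multiplier,
        so ordinary cells pass while degenerate ones are still removed.
        """
        lo = self.depth_multiplier_range[0]
        d_mean = 0.5 * sum(self.depth_multiplier_range)
        return max(1, int(0.5 * self.expected_open_peaks_per_cell() * lo / d_mean))


@dataclass
class FixtureTruth:
    """Ground truth of a generated fixture."""

    enhancer_ids: dict[str, list[str]]  # cell type -> planted enhancer peak ids
    pair_ids: list[tuple[str, str]]  # (distal peak id, promoter peak id)
    pair_genes: list[tuple[str, str]]  # (distal peak id, gene id)
    genes: list[GeneAnnotation]
    gene_of_promoter_peak: dict[str, str]
    cell_types: list[str]
    config: FixtureConfig


@dataclass
class SimulatedFixture:
    counts: sp.csr_matrix  # peaks x cells, 0/1 integer counts
    peak_set: PeakSet
    barcodes: pd.DataFrame
    truth: FixtureTruth


def _layout_peaks(config: FixtureConfig) -> PeakSet:
    spacing = config.chrom_length // config.n_peaks
    pad = (spacing - config.peak_width) // 2
    peaks = [
        GenomicInterval(
            config.chrom, i * spacing + pad, i * spacing + pad + config.peak_width
        )
        for i in range(config.n_peaks)
    ]
    return PeakSet(peaks)


def generate(
    config: FixtureConfig, outdir: str | Path | None = None
) -> SimulatedFixture:
    """Generate one fixture; optionally write it in the pipeline's formats.

    Planted co-accessible pairs use a shared latent Bernoulli: per cell,
    with probability ``pair_correlation`` both peaks copy one latent open
    state, otherwise each draws independently — giving pairwise
    correlation equal to ``pair_correlation``.
    """
    rng = np.random.default_rng(config.seed)
    peak_set = _layout_peaks(config)
    n_peaks = config.n_peaks

    # synthetic genes: TSS at selected peak midpoints (promoter peaks)
    n_prom = int(round(config.promoter_fraction * n_peaks))
    prom_idx = np.sort(rng.choice(n_peaks, size=n_prom, replace=False))
    genes: list[GeneAnnotation] = []
    gene_of_promoter_peak: dict[str, str] = {}
    for g, pi in enumerate(prom_idx):
        peak = peak_set[int(pi)]
        gid = f"gene{g}"
        exon_start = peak.end + 50
        genes.append(
            GeneAnnotation(
                gene_id=gid,
                chrom=config.chrom,
                strand="+",
                tss=peak.midpoint,
                exons=[GenomicInterval(config.chrom, exon_start, exon_start + 200)],
            )
        )
        gene_of_promoter_peak[peak_set.ids[int(pi)]] = gid

    is_prom = np.zeros(n_peaks, dtype=bool)
    is_prom[prom_idx] = True
    free = np.flatnonzero(~is_prom)

    # planted enhancers, disjoint across cell types
    type_names = [f"type{t}" for t in range(config.n_cell_types)]
    need = config.n_cell_types * config.n_planted_enhancers_per_type
    if need > len(free):
        raise ValueError("not enough non-promoter peaks for planted enhancers")
    enh_pool = rng.choice(free, size=need, replace=False)
    enhancer_idx = {
        ct: np.sort(
            enh_pool[
                t * config.n_planted_enhancers_per_type : (t + 1)
                * config.n_planted_enhancers_per_type
            ]
        )
        for t, ct in enumerate(type_names)
    }
    used = set(prom_idx.tolist()) | set(enh_pool.tolist())

    # planted co-accessible pairs: one free distal peak per promoter peak
    mids = peak_set.midpoints()
    pair_idx: list[tuple[int, int]] = []
    for pi in rng.permutation(prom_idx):
        if len(pair_idx) == config.n_coaccessible_pairs:
            break
        dist = np.abs(mids - mids[pi])
        ok = np.flatnonzero(
            (dist >= config.pair_min_distance)
            & (dist <= config.pair_max_distance)
            & ~is_prom
        )
        ok = np.array([i for i in ok if i not in used], dtype=np.intp)
        if len(ok) == 0:
            continue
        di = int(rng.choice(ok))
        used.add(di)
        pair_idx.append((di, int(pi)))
    if len(pair_idx) < config.n_coaccessible_pairs:
        raise ValueError(
            f"could only place {len(pair_idx)} of "
            f"{config.n_coaccessible_pairs} co-accessible pairs"
        )
    pair_peaks = {i for ab in pair_idx for i in ab}

    # per-cell draws
    n_cells = config.n_cell_types * config.n_cells_per_type
    lo, hi = config.depth_multiplier_range
    depth = rng.uniform(lo, hi, size=n_cells)
    cell_types = [
        type_names[c // config.n_cells_per_type] for c in range(n_cells)
    ]
    base_p = np.full(n_peaks, config.p_open_background)
    open_mat = np.zeros((n_peaks, n_cells), dtype=np.int8)
    for c in range(n_cells):
        p = base_p.copy()
        p[enhancer_idx[cell_types[c]]] = config.p_open_enhancer
        for a, b in pair_idx:
            p[a] = p[b] = 0.0  # drawn below via the latent scheme
        p = np.clip(p * depth[c], 0.0, 1.0)
        open_mat[:, c] = rng.random(n_peaks) < p
        p_pair = min(1.0, config.p_open_pair * depth[c])
        for a, b in pair_idx:
            if rng.random() < config.pair_correlation:
                z = rng.random() < p_pair
                open_mat[a, c] = open_mat[b, c] = z
            else:
                open_mat[a, c] = rng.random() < p_pair
                open_mat[b, c] = rng.random() < p_pair

    barcodes = pd.DataFrame(
        {
            "barcode": [f"cell{c:05d}" for c in range(n_cells)],
            "cell_type": cell_types,
            "dataset_id": ["sim0"] * n_cells,
        }
    )
    truth = FixtureTruth(
        enhancer_ids={
            ct: [peak_set.ids[int(i)] for i in idx]
            for ct, idx in enhancer_idx.items()
        },
        pair_ids=[
            (peak_set.ids[a], peak_set.ids[b]) for a, b in sorted(pair_idx)
        ],
        pair_genes=[
            (peak_set.ids[a], gene_of_promoter_peak[peak_set.ids[b]])
            for a, b in sorted(pair_idx)
        ],
        genes=genes,
        gene_of_promoter_peak=gene_of_promoter_peak,
        cell_types=cell_types,
        config=config,
    )
    fixture = SimulatedFixture(
        counts=sp.csr_matrix(open_mat),
        peak_set=peak_set,
        barcodes=barcodes,
        truth=truth,
    )
    if outdir is not None:
        write_fixture(fixture, outdir)
    return fixture


def write_fixture(fixture: SimulatedFixture, outdir: str | Path) -> None:
    """Write a fixture in the pipeline's input formats plus its truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_matrix_triplet(
        fixture.counts,
        fixture.peak_set,
        fixture.barcodes,
        outdir / "matrix.mtx",
        outdir / "peaks.bed",
        outdir / "barcodes.tsv",
    )
    with open(outdir / "genes.tsv", "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\texon_start\texon_end\n")
        for g in fixture.truth.genes:
            for e in g.exons:
                fh.write(
                    f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{e.start}\t{e.end}\n"
                )
    for ct, ids in sorted(fixture.truth.enhancer_ids.items()):
        ivs = [fixture.peak_set[fixture.peak_set.index_of(i)] for i in ids]
        write_bed(ivs, outdir / f"truth_enhancers_{ct}.bed")
    # distal ends of planted pairs: the peaks that satisfy the full enhancer
    # definition (high signal AND a promoter connection)
    distal = sorted(a for a, _ in fixture.truth.pair_ids)
    write_bed(
        [fixture.peak_set[fixture.peak_set.index_of(i)] for i in distal],
        outdir / "truth_pair_distal.bed",
    )
    with open(outdir / "truth_pairs.tsv", "w") as fh:
        fh.write("distal_peak\tpromoter_peak\tgene_id\n")
        for (a, b), (_, gid) in zip(
            fixture.truth.pair_ids, fixture.truth.pair_genes
        ):
            fh.write(f"{a}\t{b}\t{gid}\n")
    cfg = asdict(fixture.truth.config)
    with open(outdir / "config.tsv", "w") as fh:
        for key in sorted(cfg):
            fh.write(f"{key}\t{cfg[key]}\n")


def truth_eval(
    scores_by_type: Mapping[str, "object"],
    interactions_by_type: Mapping[str, Sequence["object"]],
    truth: FixtureTruth,
) -> pd.DataFrame:
    """Score recovery of planted structure.

    For each cell type, the AROC of the consensus score against the
    planted-enhancer labels (rank statistic over peaks); pooled over
    types, the precision and recall of predicted enhancer-gene
    interactions against the planted distal-peak/gene pairs.
    """
    from sklearn.metrics import roc_auc_score

    rows = []
    for ct, scores in scores_by_type.items():
        if ct not in truth.enhancer_ids:
            raise ValueError(f"cell type {ct!r} not present in truth")
        planted = set(truth.enhancer_ids[ct])
        unknown = planted - set(scores.peak_ids)
        if unknown:
            raise ValueError(f"truth peak ids missing from scores: {sorted(unknown)[:5]}")
        labels = np.array([pid in planted for pid in scores.peak_ids])
        auc = float(roc_auc_score(labels, scores.scores))
        rows.append(("consensus_aroc", ct, auc))

    planted_pairs = set(truth.pair_genes)
    predicted: set[tuple[str, str]] = set()
    for ct, interactions in interactions_by_type.items():
        for rec in interactions:
            predicted.add((rec.enhancer.name, rec.gene_id))
    # predicted enhancer ids are coordinate names; so are generated peak ids
    hits = len(predicted & planted_pairs)
    precision = hits / len(predicted) if predicted else 0.0
    recall = hits / len(planted_pairs) if planted_pairs else 1.0
    rows.append(("pair_precision", "all", precision))
    rows.append(("pair_recall", "all", recall))
    return pd.DataFrame(rows, columns=["metric", "scope", "value"])
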