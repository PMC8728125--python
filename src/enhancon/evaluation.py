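"""Base-pair-level evaluation of scored enhancer predictions.

Predictions are compared with a gold-standard enhancer region set over a
defined genomic universe: every base pair of the universe is one
classification instance (positive if covered by a gold region), a base
pair is predicted positive at threshold t iff covered by a prediction
scoring >= t, and sensitivity/specificity/AROC follow from exact interval
arithmetic — no binning, and partially overlapping predictions contribute
partial true-positive base pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RegionSet

__all__ = ["ScoredInterval", "EvaluationCurve", "bp_confusion", "aroc"]


@dataclass(frozen=True)
class ScoredInterval:
    interval: GenomicInterval
    score: float


@dataclass
class EvaluationCurve:
    """Confusion counts across thresholds and the resulting AROC."""

    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    aroc: float
    universe: RegionSet

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "tp": self.tp,
                "fp": self.fp,
                "tn": self.tn,
                "fn": self.fn,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def _merge(intervals: Sequence[GenomicInterval]) -> dict[str, np.ndarray]:
    """Merge into disjoint sorted (start, end) arrays per chromosome."""
    by: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, ivs in by.items():
        ivs.sort()
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


def _total(m: dict[str, np.ndarray]) -> int:
    return sum(int((a[:, 1] - a[:, 0]).sum()) for a in m.values())


def _intersect(a: dict[str, np.ndarray], b: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for chrom in set(a) & set(b):
        ia, ib = a[chrom], b[chrom]
        res = []
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i, 0], ib[j, 0])
            e = min(ia[i, 1], ib[j, 1])
            if e > s:
                res.append((s, e))
            if ia[i, 1] <= ib[j, 1]:
                i += 1
            else:
                j += 1
        if res:
            out[chrom] = np.asarray(res, dtype=np.int64)
    return out


def _confusion_merged(
    pred: dict[str, np.ndarray],
    gold_u: dict[str, np.ndarray],
    universe_m: dict[str, np.ndarray],
    n_universe: int,
    n_pos: int,
) -> tuple[int, int, int, int]:
    pred_u = _intersect(pred, universe_m)
    n_pred = _total(pred_u)
    tp = _total(_intersect(pred_u, gold_u))
    fp = n_pred - tp
    fn = n_pos - tp
    tn = n_universe - n_pos - fp
    return tp, fp, tn, fn


def bp_confusion(
    predictions: Sequence[ScoredInterval],
    gold: RegionSet,
    universe: RegionSet,
    threshold: float,
) -> tuple[int, int, int, int]:
    """Exact base-pair confusion counts (tp, fp, tn, fn) at one threshold.

    Positive bp are universe bp covered by gold; a bp is predicted
    positive iff covered by a prediction with score >= threshold.
    """
    if len(universe) == 0:
        raise ValueError("universe must be non-empty")
    if len(gold) == 0:
        raise ValueError("gold standard must be non-empty")
    universe_m = _merge(list(universe))
    gold_u = _intersect(_merge(list(gold)), universe_m)
    n_universe = _total(universe_m)
    n_pos = _total(gold_u)
    hits = [p.interval for p in predictions if p.score >= threshold]
    pred = _merge(hits) if hits else {}
    return _confusion_merged(pred, gold_u, universe_m, n_universe, n_pos)


def aroc(
    predictions: Sequence[ScoredInterval],
    gold: RegionSet,
    universe: RegionSet,
) -> EvaluationCurve:
    """Base-pair ROC curve and area over all distinct score thresholds.

    Thresholds sweep every distinct prediction score in descending order,
    with sentinels: +inf (nothing predicted) first and an implicit final
    point where every universe bp is called positive, so the curve spans
    (0,0) to (1,1). The area is by trapezoidal integration over
    (1 - specificity, sensitivity). AROC is invariant under strictly
    monotone transforms of the scores.
    """
    if len(universe) == 0:
        raise ValueError("universe must be non-empty")
    if len(gold) == 0:
        raise ValueError("gold standard must be non-empty")
    universe_m = _merge(list(universe))
    gold_u = _intersect(_merge(list(gold)), universe_m)
    n_universe = _total(universe_m)
    n_pos = _total(gold_u)
    if n_pos == 0:
        raise ValueError("gold standard does not intersect the universe")
    n_neg = n_universe - n_pos
    if n_neg == 0:
        raise ValueError(
            "universe contains no negative base pairs (it is fully covered "
            "by the gold standard); pass a wider universe"
        )

    scores = sorted({p.score for p in predictions}, reverse=True)
    if not scores:
        warnings.warn("no predictions: AROC degenerates to 0.5", RuntimeWarning, stacklevel=2)
    thresholds = [np.inf] + scores + [-np.inf]
    tp, fp, tn, fn = [], [], [], []
    for t in thresholds:
        if t == -np.inf:
            # everything positive
            c = (n_pos, n_neg, 0, 0)
        else:
            hits = [p.interval for p in predictions if p.score >= t]
            pred = _merge(hits) if hits else {}
            c = _confusion_merged(pred, gold_u, universe_m, n_universe, n_pos)
        tp.append(c[0])
        fp.append(c[1])
        tn.append(c[2])
        fn.append(c[3])
    tp, fp, tn, fn = map(lambda x: np.asarray(x, dtype=np.int64), (tp, fp, tn, fn))
    sens = tp / n_pos
    spc = tn / n_neg
    fpr = 1.0 - spc
    area = float(np.trapezoid(sens, fpr))
    return EvaluationCurve(
        thresholds=np.asarray(thresholds, dtype=float),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spc,
        aroc=area,
        universe=universe,
    )
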