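"""Accuracy harness: intron-chain matching, precision/recall, PRC, pAUC.

A predicted multi-exon transcript matches when its intron chain equals
a reference transcript's exactly (chrom/strand aware).  Duplicate
predicted chains count once (set semantics).  Single-exon transcripts
are excluded from both sides.  Sweeping a ranking parameter (score or
abundance) over a grid yields a precision-recall curve; the partial
area under it, restricted to a recall (or precision) interval, is the
summary statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

ChainKey = tuple[str, str, tuple[tuple[int, int], ...]]


def _chain_set(items: Iterable) -> set[ChainKey]:
    out = set()
    for it in items:
        if isinstance(it, tuple):
            key = it
        else:
            key = (it.chrom, it.strand, tuple(it.intron_chain))
        if key[2]:  # multi-exon only
            out.add(key)
    return out


def match_count(predicted: Iterable, truth: Iterable) -> int:
    """Number of distinct predicted intron chains with an exact match."""
    return len(_chain_set(predicted) & _chain_set(truth))


def precision_recall(predicted: Iterable, truth: Iterable) -> tuple[float, float]:
    """(precision, recall) of distinct multi-exon chains."""
    pred = _chain_set(predicted)
    ref = _chain_set(truth)
    if not ref:
        raise ValueError("empty truth set: evaluation is meaningless")
    matched = len(pred & ref)
    precision = matched / len(pred) if pred else 0.0
    recall = matched / len(ref)
    return precision, recall


@dataclass
class PRCurve:
    thresholds: list[float]
    precisions: list[float]
    recalls: list[float]
    matched: list[int]

    def points(self) -> list[tuple[float, float, float]]:
        return list(zip(self.thresholds, self.precisions, self.recalls))


def prc_curve(
    scored: Sequence[tuple[ChainKey, float]],
    truth: Iterable,
    grid: Optional[Sequence[float]] = None,
) -> PRCurve:
    """Precision-recall curve of (chain, ranking-value) pairs over a
    threshold grid (default: the distinct ranking values)."""
    ref = _chain_set(truth)
    if not ref:
        raise ValueError("empty truth set: evaluation is meaningless")
    # collapse duplicate chains: keep the best value per chain
    best: dict[ChainKey, float] = {}
    for key, val in scored:
        if key[2] and (key not in best or val > best[key]):
            best[key] = val
    if grid is None:
        grid = sorted(set(best.values()))
    thresholds, precisions, recalls, matched = [], [], [], []
    for th in sorted(grid):
        kept = [k for k, v in best.items() if v >= th]
        m = len(set(kept) & ref)
        thresholds.append(float(th))
        precisions.append(m / len(kept) if kept else 0.0)
        recalls.append(m / len(ref))
        matched.append(m)
    return PRCurve(thresholds=thresholds, precisions=precisions, recalls=recalls, matched=matched)


def pauc(curve: PRCurve, recall_range: Optional[tuple[float, float]] = None) -> float:
    """Trapezoidal area under precision(recall), restricted to
    ``recall_range`` (defaults to the curve's own recall span)."""
    pts = sorted(zip(curve.recalls, curve.precisions))
    rec = np.array([r for r, _ in pts])
    pre = np.array([p for _, p in pts])
    if recall_range is None:
        lo, hi = float(rec.min()), float(rec.max())
        if hi <= lo:
            return 0.0  # degenerate single-point curve
    else:
        lo, hi = recall_range
        if hi <= lo:
            raise ValueError("empty recall restriction interval")
    grid = np.unique(np.concatenate([rec, [lo, hi]]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size < 2:
        return 0.0
    interp = np.interp(grid, rec, pre)
    return float(np.trapezoid(interp, grid))


def shared_recall_range(a: PRCurve, b: PRCurve) -> tuple[float, float]:
    """Intersection of two curves' recall spans (for comparable pAUCs)."""
    lo = max(min(a.recalls), min(b.recalls))
    hi = min(max(a.recalls), max(b.recalls))
    return lo, hi


def prc_and_pauc(
    scored: Sequence[tuple[ChainKey, float]],
    truth: Iterable,
    grid: Optional[Sequence[float]] = None,
    recall_range: Optional[tuple[float, float]] = None,
) -> tuple[PRCurve, float]:
    curve = prc_curve(scored, truth, grid=grid)
    return curve, pauc(curve, recall_range=recall_range)
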