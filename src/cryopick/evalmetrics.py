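"""Scoring picked particles against ground truth.

A pick matches an unmatched ground-truth particle when their centers are
within the tolerance (default: that particle's own radius). Matching is
greedy in ascending center distance — order-independent and one-to-one —
with an optimal bipartite matcher available for verification. Precision,
recall and F1 summarize the matched counts; Dice compares masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io_star import ParticleSet


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    dice: float | None = None
    match_tol: float | None = None

    def as_dict(self):
        d = {k: v for k, v in self.__dict__.items()}
        return d


def _prf(tp, fp, fn):
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall)
        else 0.0
    )
    return precision, recall, f1


def _distance_tol_pairs(picks: ParticleSet, gt: ParticleSet, match_tol):
    pairs = []
    for i, p in enumerate(picks):
        for j, g in enumerate(gt):
            tol = g.radius if match_tol is None else match_tol
            d = math.hypot(p.x - g.x, p.y - g.y)
            if d <= tol:
                pairs.append((d, i, j))
    return pairs


def match_and_score(picks: ParticleSet, gt: ParticleSet, match_tol=None,
                    optimal=False) -> EvalResult:
    """Count TP/FP/FN by one-to-one center matching.

    ``match_tol`` is a fixed pixel tolerance; None uses each ground-truth
    particle's radius. ``optimal`` switches the greedy matcher for an
    exact maximum bipartite matching (slower; used for verification).
    """
    pairs = _distance_tol_pairs(picks, gt, match_tol)
    if optimal:
        tp = _optimal_match_count(len(picks), len(gt), pairs)
    else:
        pairs.sort()
        used_p, used_g = set(), set()
        tp = 0
        for _, i, j in pairs:
            if i in used_p or j in used_g:
                continue
            used_p.add(i)
            used_g.add(j)
            tp += 1
    fp, fn = len(picks) - tp, len(gt) - tp
    precision, recall, f1 = _prf(tp, fp, fn)
    return EvalResult(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
                      f1=f1, match_tol=match_tol)


def _optimal_match_count(n_picks, n_gt, pairs) -> int:
    """Maximum-cardinality matching on the tolerance graph."""
    if not pairs:
        return 0
    # linear_sum_assignment on a reward matrix: 1 for admissible pairs
    reward = np.zeros((n_picks, n_gt))
    for _, i, j in pairs:
        reward[i, j] = 1.0
    ri, cj = linear_sum_assignment(-reward)
    return int(reward[ri, cj].sum())


def mask_dice(pred_mask, gt_mask) -> float:
    """Dice overlap 2|A&B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(gt_mask, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / denom


def particles_to_mask(pset: ParticleSet, shape) -> np.ndarray:
    """Rasterize particle footprints (disks) into a binary mask."""
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for p in pset:
        mask |= (xx - p.x) ** 2 + (yy - p.y) ** 2 <= p.radius**2
    return mask
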