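"""Instance-mask proposals from a semantic probability map.

Two pluggable proposers share one output contract (a list of
InstanceProposal, sorted by score):

* ``classical_propose`` (default, no downloads): threshold the semantic
  map, split touching particles by watershed on the distance transform,
  score each segment by its mean foreground probability.
* ``sam_propose``: an adapter around a promptable instance-segmentation
  backend (SAM-style automatic mask generation from a uniform prompt
  grid). The backend and its weights are an optional external dependency;
  without them the adapter raises — it never silently falls back.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed


@dataclass(frozen=True)
class InstanceProposal:
    """One candidate particle instance in the network frame."""

    mask: np.ndarray
    bbox: tuple  # (x0, y0, x1, y1), half-open
    score: float
    area: int
    diagonal: float

    @classmethod
    def from_mask(cls, mask, score) -> "InstanceProposal":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("proposal mask is empty")
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score must be in [0,1], got {score}")
        ys, xs = np.nonzero(mask)
        bbox = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
        area = int(mask.sum())
        diagonal = math.hypot(bbox[2] - bbox[0], bbox[3] - bbox[1])
        return cls(mask=mask, bbox=bbox, score=float(score), area=area,
                   diagonal=diagonal)

    def validate(self):
        ys, xs = np.nonzero(self.mask)
        tight = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
        if tight != tuple(self.bbox):
            raise AssertionError(f"bbox {self.bbox} is not tight ({tight})")
        if self.area != int(self.mask.sum()):
            raise AssertionError("area does not match mask")
        d = math.hypot(self.bbox[2] - self.bbox[0], self.bbox[3] - self.bbox[1])
        if abs(d - self.diagonal) > 1e-9:
            raise AssertionError("diagonal does not match bbox")
        return self


@dataclass
class ProposerConfig:
    threshold: float = 0.5
    min_seed_separation: float | None = None  # pixels; None = adaptive
    points_per_side: int = 32  # SAM prompt grid
    dedup_iou: float = 0.9


def _sort_key(p: InstanceProposal):
    return (-p.score, p.bbox[1], p.bbox[0])


def classical_propose(prob, cfg: ProposerConfig = ProposerConfig()):
    """Watershed-based proposals from the semantic probability map.

    Binarize at the threshold, seed at maxima of the distance transform
    (minimum separation adaptive to the median component size), split by
    watershed; each segment scores its mean probability. Deterministic;
    sorted by score descending (ties by bbox top-left).
    """
    prob = np.asarray(prob, dtype=np.float64)
    fg = prob >= cfg.threshold
    if not fg.any():
        return []
    labels, n = ndimage.label(fg)
    if cfg.min_seed_separation is not None:
        sep = cfg.min_seed_separation
    else:
        # 0.5 x median equivalent diameter of the current components
        areas = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
        med_d = float(np.median(2.0 * np.sqrt(areas / np.pi)))
        sep = max(1.0, 0.5 * med_d)
    dist = ndimage.distance_transform_edt(fg)
    seeds = peak_local_max(
        dist, min_distance=max(1, int(round(sep))), labels=labels,
        exclude_border=False,
    )
    markers = np.zeros_like(labels)
    for i, (y, x) in enumerate(seeds, start=1):
        markers[y, x] = i
    if markers.max() == 0:
        markers = labels
    segments = watershed(-dist, markers=markers, mask=fg)
    proposals = []
    for seg_id in range(1, segments.max() + 1):
        mask = segments == seg_id
        if not mask.any():
            continue
        score = float(np.clip(prob[mask].mean(), 0.0, 1.0))
        proposals.append(InstanceProposal.from_mask(mask, score))
    return sorted(proposals, key=_sort_key)


def mask_iou(a, b) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return float(inter / union) if union else 0.0


def sam_propose(image, cfg: ProposerConfig = ProposerConfig(), backend=None):
    """Adapter for a SAM-style automatic mask generator.

    ``backend`` must expose ``generate(image) -> iterable of dicts`` with
    keys ``segmentation`` (bool mask) and ``predicted_iou``; each mask
    becomes an InstanceProposal scored by the backend's predicted IoU.
    Near-duplicate masks (IoU > ``dedup_iou``) keep the higher score.
    """
    if backend is None:
        raise RuntimeError(
            "no instance-segmentation backend provided: the SAM proposer "
            "needs externally supplied weights (segment-anything is an "
            "optional dependency). Use `--proposer classical` instead."
        )
    image = np.asarray(image)
    raw = []
    for rec in backend.generate(image):
        mask = np.asarray(rec["segmentation"], dtype=bool)
        if mask.shape != image.shape:
            raise ValueError("backend mask shape differs from the image")
        if not mask.any():
            continue
        score = float(np.clip(rec["predicted_iou"], 0.0, 1.0))
        raw.append(InstanceProposal.from_mask(mask, score))
    raw.sort(key=_sort_key)
    kept = []
    for p in raw:  # score-descending: the first of a duplicate pair wins
        if all(mask_iou(p.mask, q.mask) <= cfg.dedup_iou for q in kept):
            kept.append(p)
    for p in kept:
        p.validate()
    return kept
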