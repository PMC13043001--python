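"""Semantic-instance collaborative filtering of particle proposals.

Three sequential filters turn raw instance proposals into high-confidence
picks:

1. confidence: keep proposals with quality score >= tau_conf (0.80);
2. adaptive size: keep proposals whose bounding-box diagonal lies within
   k standard deviations of the median diagonal (plus minimum-area and
   aspect-ratio sanity bounds) — contaminants are size outliers;
3. semantic consistency: keep proposals whose mask has IoU >= tau_sem
   (0.30) with the semantic foreground, computed against the union of
   semantic connected components the proposal touches.

Survivors are reduced to (center, radius, confidence) particles and
rescaled to the original micrograph frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_star import Particle, ParticleSet, rescale_coordinates
from .proposals import InstanceProposal


@dataclass
class FilterConfig:
    tau_conf: float = 0.80
    tau_sem: float = 0.30
    k_diag: float = 2.0
    min_area: int = 16
    max_aspect: float = 2.5
    radius_mode: str = "equivalent_area"
    dedup_center_factor: float = 0.5  # x min(radii) for duplicate suppression

    def __post_init__(self):
        if self.radius_mode not in ("equivalent_area", "half_max_box_side"):
            raise ValueError(f"unknown radius_mode {self.radius_mode!r}")
        if not self.max_aspect > 1:
            raise ValueError("max_aspect must exceed 1")


def confidence_filter(props, cfg: FilterConfig):
    """Keep proposals with score >= tau_conf; order preserved."""
    return [p for p in props if p.score >= cfg.tau_conf]


def size_filter(props, cfg: FilterConfig):
    """Adaptive diagonal filter plus area/aspect sanity bounds.

    The diagonal criterion uses the median and standard deviation of all
    input diagonals and is skipped when fewer than 3 proposals are
    available (the spread is degenerate); area and aspect still apply.
    """
    if not props:
        return []
    use_diag = len(props) >= 3
    if use_diag:
        diags = np.array([p.diagonal for p in props], dtype=np.float64)
        med, sd = float(np.median(diags)), float(diags.std())
    kept = []
    for p in props:
        if use_diag and abs(p.diagonal - med) > cfg.k_diag * sd:
            continue
        if p.area < cfg.min_area:
            continue
        w, h = p.bbox[2] - p.bbox[0], p.bbox[3] - p.bbox[1]
        if max(w / h, h / w) > cfg.max_aspect:
            continue
        kept.append(p)
    return kept


def semantic_iou(prop: InstanceProposal, sem_labels, sem_areas) -> float:
    """IoU of a proposal against the union of semantic components it touches.

    Computing IoU against the whole foreground mask would be degenerate
    (roughly instance_area / total_foreground on a dense micrograph); the
    component-local reading keeps the 0.30 threshold meaningful.
    """
    touched = np.unique(sem_labels[prop.mask])
    touched = touched[touched > 0]
    if touched.size == 0:
        return 0.0
    overlap = int(np.isin(sem_labels[prop.mask], touched).sum())
    union = prop.area + int(sem_areas[touched - 1].sum()) - overlap
    return overlap / union if union else 0.0


def semantic_consistency_filter(props, sem_mask, cfg: FilterConfig):
    """Keep proposals with component-local semantic IoU >= tau_sem."""
    sem_mask = np.asarray(sem_mask, dtype=bool)
    for p in props:
        if p.mask.shape != sem_mask.shape:
            raise ValueError(
                f"frame mismatch: proposal {p.mask.shape} vs semantic "
                f"mask {sem_mask.shape}"
            )
    sem_labels, n = ndimage.label(sem_mask)
    sem_areas = ndimage.sum_labels(
        sem_mask, sem_labels, index=np.arange(1, n + 1)
    )
    return [
        p for p in props if semantic_iou(p, sem_labels, sem_areas) >= cfg.tau_sem
    ]


def apply_filters(props, sem_mask, cfg: FilterConfig):
    """The three-stage filter cascade; each stage contracts its input."""
    out = confidence_filter(props, cfg)
    out = size_filter(out, cfg)
    return semantic_consistency_filter(out, sem_mask, cfg)


def _radius(p: InstanceProposal, cfg: FilterConfig) -> float:
    if cfg.radius_mode == "equivalent_area":
        return math.sqrt(p.area / math.pi)
    w, h = p.bbox[2] - p.bbox[0], p.bbox[3] - p.bbox[1]
    return max(w, h) / 2.0


def extract_particles(props, source_shape, net_shape, cfg: FilterConfig,
                      micrograph_id="") -> ParticleSet:
    """Reduce filtered proposals to particles in the original frame.

    Center = mask centroid, radius = equivalent-area circle radius (or
    half the longer box side), confidence = proposal score. Near-duplicate
    centers (closer than ``dedup_center_factor * min(radii)``) keep the
    higher score.
    """
    particles = []
    for p in props:
        cy, cx = ndimage.center_of_mass(p.mask)
        particles.append(
            Particle(x=float(cx), y=float(cy), radius=_radius(p, cfg),
                     confidence=p.score)
        )
    pset = ParticleSet(
        micrograph_id=micrograph_id,
        particles=particles,
        source_shape=tuple(net_shape),
    )
    pset = rescale_coordinates(pset, net_shape, source_shape)
    # duplicate suppression in the output frame, best score first
    order = sorted(pset.particles, key=lambda q: -q.confidence)
    kept = []
    for q in order:
        close = any(
            math.hypot(q.x - r.x, q.y - r.y)
            < cfg.dedup_center_factor * min(q.radius, r.radius)
            for r in kept
        )
        if not close:
            kept.append(q)
    return ParticleSet(
        micrograph_id=micrograph_id, particles=kept,
        source_shape=tuple(source_shape),
    ).validate()


def collaborative_pick(prob, props, source_shape, cfg: FilterConfig,
                       micrograph_id="", sem_threshold=0.5) -> ParticleSet:
    """Full collaborative mechanism: the filter cascade + extraction."""
    sem_mask = np.asarray(prob) >= sem_threshold
    survivors = apply_filters(props, sem_mask, cfg)
    return extract_particles(
        survivors, source_shape, np.asarray(prob).shape, cfg,
        micrograph_id=micrograph_id,
    )
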