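"""Segmentation losses and the deep-supervised training objective.

The objective combines pixel-wise binary cross-entropy, soft Dice overlap
and Focal loss on the main head,

    L = lambda1*L_BCE + lambda2*L_Dice + lambda3*L_Focal
        + sum_j mu_j * (L_BCE^j + L_Dice^j),

with auxiliary BCE+Dice terms on the three deep-supervision heads.
Defaults: lambda = (1, 1, 0.5), mu = (0.4, 0.3, 0.2).

Two parallel implementations live here: plain-numpy functions (the public
API) and autodiff-tensor versions used by the trainer. They share the
same formulas and are cross-checked in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import tensor as T


@dataclass
class LossWeights:
    """Weights and constants of the combined objective.

    ``alpha``/``gamma`` are the Focal-loss constants (canonical 0.25/2.0);
    ``eps`` floors the log arguments, ``dice_smooth`` regularizes empty
    masks.
    """

    lambda_bce: float = 1.0
    lambda_dice: float = 1.0
    lambda_focal: float = 0.5
    mu: tuple[float, float, float] = (0.4, 0.3, 0.2)
    alpha: float = 0.25
    gamma: float = 2.0
    eps: float = 1e-7
    dice_smooth: float = 1e-6


@dataclass
class SemanticOutput:
    """Per-pixel foreground probabilities plus deep-supervision heads."""

    prob: np.ndarray
    aux_probs: list = field(default_factory=list)
    logits: np.ndarray | None = None
    aux_logits: list = field(default_factory=list)


def _check(p, y):
    p, y = np.asarray(p, dtype=np.float64), np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    return p, y


def bce_loss(p, y, w: LossWeights = LossWeights()) -> float:
    """Mean binary cross-entropy; probabilities clamped to [eps, 1-eps]."""
    p, y = _check(p, y)
    p = np.clip(p, w.eps, 1.0 - w.eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def dice_loss(p, y, w: LossWeights = LossWeights()) -> float:
    """1 - soft Dice overlap, smoothed by ``dice_smooth``."""
    p, y = _check(p, y)
    s = w.dice_smooth
    return float(1.0 - (2.0 * np.sum(p * y) + s) / (np.sum(p) + np.sum(y) + s))


def focal_loss(p, y, w: LossWeights = LossWeights()) -> float:
    """Mean Focal loss; reduces to BCE exactly at gamma=0, alpha=1."""
    p, y = _check(p, y)
    p = np.clip(p, w.eps, 1.0 - w.eps)
    pt = np.where(y > 0.5, p, 1.0 - p)
    return float(np.mean(-w.alpha * (1.0 - pt) ** w.gamma * np.log(pt)))


def total_loss(out: SemanticOutput, y, w: LossWeights = LossWeights()):
    """Deep-supervised objective.

    Returns (total, breakdown); the breakdown lists the main-head terms
    and each auxiliary head's BCE+Dice contribution. With all mu_j = 0
    the total equals the weighted main-head (backbone) loss exactly.
    """
    if any(m != 0.0 for m in w.mu) and len(out.aux_probs) != 3:
        raise ValueError(
            f"deep supervision expects 3 auxiliary heads, got {len(out.aux_probs)}"
        )
    b = bce_loss(out.prob, y, w)
    d = dice_loss(out.prob, y, w)
    f = focal_loss(out.prob, y, w)
    total = w.lambda_bce * b + w.lambda_dice * d + w.lambda_focal * f
    breakdown = {"main_bce": b, "main_dice": d, "main_focal": f}
    for j, aux in enumerate(out.aux_probs):
        bj, dj = bce_loss(aux, y, w), dice_loss(aux, y, w)
        breakdown[f"aux{j + 1}_bce"] = bj
        breakdown[f"aux{j + 1}_dice"] = dj
        mu = w.mu[j] if j < len(w.mu) else 0.0
        total += mu * (bj + dj)
    return float(total), breakdown


# -- autodiff versions (training path) ----------------------------------------

def bce_loss_t(p: nn.Tensor, y: nn.Tensor, w: LossWeights) -> nn.Tensor:
    pc = T.clamp(p, w.eps, 1.0 - w.eps)
    return T.reduce_mean(
        -(y * T.log(pc) + (1.0 - y) * T.log(1.0 - pc))
    )


def dice_loss_t(p: nn.Tensor, y: nn.Tensor, w: LossWeights) -> nn.Tensor:
    s = w.dice_smooth
    num = 2.0 * T.reduce_sum(p * y) + s
    den = T.reduce_sum(p) + T.reduce_sum(y) + s
    return 1.0 - num / den


def focal_loss_t(p: nn.Tensor, y: nn.Tensor, w: LossWeights) -> nn.Tensor:
    pc = T.clamp(p, w.eps, 1.0 - w.eps)
    pt = y * pc + (1.0 - y) * (1.0 - pc)
    return T.reduce_mean(-w.alpha * T.power(1.0 - pt, w.gamma) * T.log(pt))


def total_loss_t(prob: nn.Tensor, aux_probs, y: nn.Tensor, w: LossWeights):
    """Tensor version of :func:`total_loss`; returns (total, breakdown)."""
    b, d, f = bce_loss_t(prob, y, w), dice_loss_t(prob, y, w), focal_loss_t(prob, y, w)
    total = w.lambda_bce * b + w.lambda_dice * d + w.lambda_focal * f
    breakdown = {
        "main_bce": float(b.data),
        "main_dice": float(d.data),
        "main_focal": float(f.data),
    }
    for j, aux in enumerate(aux_probs):
        mu = w.mu[j] if j < len(w.mu) else 0.0
        bj, dj = bce_loss_t(aux, y, w), dice_loss_t(aux, y, w)
        breakdown[f"aux{j + 1}_bce"] = float(bj.data)
        breakdown[f"aux{j + 1}_dice"] = float(dj.data)
        if mu != 0.0:
            total = total + mu * (bj + dj)
    return total, breakdown
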