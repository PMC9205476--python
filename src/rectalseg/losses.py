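"""Training objective: per-channel Dice loss plus a weighted staging loss.

The combined objective is

    Loss = Loss_SEG + lambda * Loss_STG

where ``Loss_SEG`` is the mean soft Dice loss over the three structure
channels (evaluated only when ground-truth masks exist) and ``Loss_STG``
is a stage-supervision term evaluated for every case:

    p_staging = max_i  p_tumor[i] * (1 - p_rectum[i])
    Loss_STG  = -[ (1 - g) / 2 + g * p_staging ],   g in {-1, +1}

``p_staging`` is a differentiable surrogate for "some tumor exists
outside the rectum": it is large when any voxel has high tumor
probability and low rectum probability.  For a >=T3 case (g = +1) the
loss is ``-p_staging`` and decreases as the network pushes tumor outside
the rectum; for a <=T2 case (g = -1) it is ``p_staging - 1`` and
penalizes any extramural tumor probability.  Its range is [-1, 0] and
``d Loss_STG / d p_staging = -g`` exactly.

The max in ``p_staging`` is a hard max; gradients flow through the
argmax voxel (subgradient).  A temperature-smoothed variant is available
for experiments but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import ProbMaps, SegLabels, StageLabel, ValidationError

__all__ = [
    "LossConfig",
    "dice_loss",
    "dice_loss_grad",
    "staging_probability",
    "staging_probability_argmax",
    "staging_probability_smooth",
    "staging_loss",
    "combined_loss",
    "combined_loss_grad",
]

#: Default Dice smoothing term, added to numerator and denominator.
DICE_EPS = 1.0


@dataclass
class LossConfig:
    """Weights and switches of the combined objective."""

    lam: float = 0.02
    dice_eps: float = DICE_EPS
    staging_enabled: bool = True

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValidationError(f"lambda must be >= 0, got {self.lam}")
        if self.dice_eps < 0:
            raise ValidationError(f"dice_eps must be >= 0, got {self.dice_eps}")


def _check_probs(p: np.ndarray, name: str = "p") -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        raise ValidationError(f"{name} is empty")
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ValidationError(f"{name} has values outside [0, 1]")
    return p


def dice_loss(p: np.ndarray, g: np.ndarray, eps: float = DICE_EPS) -> float:
    """Soft Dice loss ``1 - (2 sum(p g) + eps) / (sum(p) + sum(g) + eps)``.

    ``eps`` smooths the empty-mask case (both empty -> 0) and stabilizes
    gradients; with ``eps = 0`` this is the plain Dice loss.
    """
    p = _check_probs(p)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValidationError(f"shape mismatch: p {p.shape} vs g {g.shape}")
    num = 2.0 * float((p * g).sum()) + eps
    den = float(p.sum()) + float(g.sum()) + eps
    if den == 0.0:  # only possible when eps == 0 and both are empty
        return 0.0
    return 1.0 - num / den


def dice_loss_grad(p: np.ndarray, g: np.ndarray, eps: float = DICE_EPS) -> np.ndarray:
    """Gradient of :func:`dice_loss` with respect to ``p`` (same shape)."""
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    num = 2.0 * float((p * g).sum()) + eps
    den = float(p.sum()) + float(g.sum()) + eps
    if den == 0.0:
        return np.zeros_like(p)
    return (num - 2.0 * g * den) / (den * den)


def staging_probability(p_maps: ProbMaps) -> float:
    """``max_i p_tumor[i] * (1 - p_rectum[i])`` over all voxels."""
    score = p_maps.tumor * (1.0 - p_maps.rectum)
    return float(score.max())


def staging_probability_argmax(tumor: np.ndarray, rectum: np.ndarray) -> tuple[float, tuple]:
    """Staging probability plus the (first) argmax voxel index."""
    score = np.asarray(tumor) * (1.0 - np.asarray(rectum))
    flat = int(np.argmax(score))
    idx = np.unravel_index(flat, score.shape)
    return float(score[idx]), idx


def staging_probability_smooth(p_maps: ProbMaps, temperature: float = 0.01) -> float:
    """Temperature-smoothed (log-sum-exp) variant of the staging max."""
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    score = (p_maps.tumor * (1.0 - p_maps.rectum)).ravel()
    m = score.max()
    return float(m + temperature * np.log(np.mean(np.exp((score - m) / temperature))))


def staging_loss(p_staging: float, label: StageLabel) -> float:
    """``-[(1 - g)/2 + g * p_staging]``; range [-1, 0]; slope is ``-g``."""
    if not 0.0 - 1e-9 <= p_staging <= 1.0 + 1e-9:
        raise ValidationError(f"p_staging must be in [0, 1], got {p_staging}")
    g = label.g_staging
    return -((1.0 - g) / 2.0 + g * float(p_staging))


def combined_loss(
    p_maps: ProbMaps,
    labels: Optional[SegLabels],
    stage: StageLabel,
    cfg: Optional[LossConfig] = None,
) -> float:
    """Per-case objective: mean Dice loss (if masks exist) + lambda * staging loss.

    With ``lam = 0`` (or ``staging_enabled = False``) this reduces exactly
    to the mean Dice loss, the dice-only ablation arm.
    """
    cfg = cfg or LossConfig()
    total = 0.0
    if labels is not None:
        if labels.shape != p_maps.shape:
            raise ValidationError(
                f"label shape {labels.shape} does not match probabilities {p_maps.shape}"
            )
        pred = p_maps.stack()
        truth = labels.stack().astype(np.float64)
        total += float(
            np.mean([dice_loss(pred[c], truth[c], cfg.dice_eps) for c in range(3)])
        )
    if cfg.staging_enabled and cfg.lam > 0:
        total += cfg.lam * staging_loss(staging_probability(p_maps), stage)
    return total


def combined_loss_grad(
    p_stack: np.ndarray,
    labels: Optional[SegLabels],
    stage: StageLabel,
    cfg: Optional[LossConfig] = None,
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. a ``(3, D, H, W)`` probability stack.

    Used by the trainer; the staging gradient flows through the argmax
    voxel of ``p_tumor * (1 - p_rectum)`` only (hard max subgradient).
    """
    cfg = cfg or LossConfig()
    p_stack = np.asarray(p_stack, dtype=np.float64)
    grad = np.zeros_like(p_stack)
    total = 0.0
    if labels is not None:
        truth = labels.stack().astype(np.float64)
        for c in range(3):
            total += dice_loss(p_stack[c], truth[c], cfg.dice_eps) / 3.0
            grad[c] += dice_loss_grad(p_stack[c], truth[c], cfg.dice_eps) / 3.0
    if cfg.staging_enabled and cfg.lam > 0:
        p_stg, idx = staging_probability_argmax(p_stack[0], p_stack[1])
        total += cfg.lam * staging_loss(p_stg, stage)
        g = stage.g_staging
        # d/dp_tumor[idx] = -g (1 - p_rectum[idx]);  d/dp_rectum[idx] = g p_tumor[idx]
        grad[(0, *idx)] += cfg.lam * (-g) * (1.0 - p_stack[(1, *idx)])
        grad[(1, *idx)] += cfg.lam * g * p_stack[(0, *idx)]
    return total, grad
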