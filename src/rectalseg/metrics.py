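"""Evaluation metrics: DSC, staging confusion table, summary statistics.

DSC(P, G) = 2 |P ∩ G| / (|P| + |G|); 1.0 means complete overlap.  The
staging confusion table treats >=T3 as the positive class, so
sensitivity = tp / (tp + fn) is the fraction of >=T3 cases recognized
and specificity = tn / (tn + fp) the fraction of <=T2 cases spared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .core import StageCategory, StageLabel, StagePrediction, ValidationError

__all__ = [
    "ConfusionTable2x2",
    "DscSummary",
    "dsc",
    "staging_confusion",
    "sensitivity",
    "specificity",
    "accuracy",
    "tumor_diameter",
    "summarize_dsc",
]


@dataclass(frozen=True)
class ConfusionTable2x2:
    """Binary staging contingency counts (positive class: >=T3)."""

    tp: int  # predicted >=T3, truth >=T3
    fp: int  # predicted >=T3, truth <=T2
    fn: int  # predicted <=T2, truth >=T3
    tn: int  # predicted <=T2, truth <=T2

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionTable2x2") -> "ConfusionTable2x2":
        return ConfusionTable2x2(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


@dataclass(frozen=True)
class DscSummary:
    """Median and interquartile range of a list of DSC values."""

    values: tuple[float, ...]
    median: float
    iqr: tuple[float, float]  # (25th, 75th percentile)


def dsc(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Dice similarity coefficient between two binary masks.

    Both masks empty is defined as 1.0 (perfect agreement on absence).
    """
    p = np.asarray(pred_mask).astype(bool)
    g = np.asarray(truth_mask).astype(bool)
    if p.shape != g.shape:
        raise ValidationError(f"mask shapes differ: {p.shape} vs {g.shape}")
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(p & g)) / denom


def staging_confusion(
    preds: Sequence[Union[StagePrediction, StageLabel]],
    truths: Sequence[StageLabel],
) -> ConfusionTable2x2:
    """Tally predicted vs ground-truth binary stages."""
    if len(preds) != len(truths):
        raise ValidationError(f"length mismatch: {len(preds)} preds vs {len(truths)} truths")
    if len(preds) == 0:
        raise ValidationError("need at least one (prediction, truth) pair")
    tp = fp = fn = tn = 0
    for pred, truth in zip(preds, truths):
        pc = pred.category
        pos = pc is StageCategory.GE_T3
        true_pos = truth.category is StageCategory.GE_T3
        if pos and true_pos:
            tp += 1
        elif pos and not true_pos:
            fp += 1
        elif not pos and true_pos:
            fn += 1
        else:
            tn += 1
    return ConfusionTable2x2(tp=tp, fp=fp, fn=fn, tn=tn)


def sensitivity(t: ConfusionTable2x2) -> float:
    """tp / (tp + fn); NaN when there are no >=T3 truths."""
    denom = t.tp + t.fn
    return t.tp / denom if denom else math.nan


def specificity(t: ConfusionTable2x2) -> float:
    """tn / (tn + fp); NaN when there are no <=T2 truths."""
    denom = t.tn + t.fp
    return t.tn / denom if denom else math.nan


def accuracy(t: ConfusionTable2x2) -> float:
    """(tp + tn) / total; NaN for an empty table."""
    return (t.tp + t.tn) / t.total if t.total else math.nan


def tumor_diameter(mask: np.ndarray, spacing_mm: Sequence[float]) -> float:
    """Largest axis-aligned bounding-box extent of the mask, in mm.

    A deterministic approximation of the maximum tumor diameter (a true
    Feret diameter can only be larger by a bounded factor).
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValidationError("tumor_diameter requires a nonempty mask")
    idx = np.argwhere(mask)
    extent_vox = idx.max(axis=0) - idx.min(axis=0) + 1
    return float(np.max(extent_vox * np.asarray(spacing_mm, dtype=float)))


def summarize_dsc(values: Sequence[float]) -> DscSummary:
    """Median and 25th-75th percentile range of DSC values."""
    if len(values) == 0:
        raise ValidationError("summarize_dsc requires a nonempty list")
    arr = np.asarray(values, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValidationError("DSC values must lie in [0, 1]")
    q25, med, q75 = np.percentile(arr, [25.0, 50.0, 75.0])
    return DscSummary(values=tuple(arr.tolist()), median=float(med), iqr=(float(q25), float(q75)))
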