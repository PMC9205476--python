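"""Binarization of probability maps and the geometric T2/T3 rule.

A case is >=T3 exactly when at least one predicted tumor voxel lies
outside the predicted rectum mask (the rectum mask includes its own
contour, so "completely included in the rectum" and "no tumor voxel
outside the rectum mask" coincide).  An optional stricter mode also
calls >=T3 when the tumor touches the outer rectum boundary from inside.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import (
    ProbMaps,
    SegLabels,
    StageCategory,
    StageLabel,
    StagePrediction,
    ValidationError,
)

__all__ = ["binarize", "classify_stage", "stage_prediction_to_label"]


def binarize(p_maps: ProbMaps, threshold: float = 0.5) -> SegLabels:
    """Threshold each channel independently; a voxel is set iff p > threshold.

    The inequality is strict, so a probability exactly at the threshold
    maps to background.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    return SegLabels(
        tumor=p_maps.tumor > threshold,
        rectum=p_maps.rectum > threshold,
        mesorectum=p_maps.mesorectum > threshold,
    )


def classify_stage(masks: SegLabels, contour_strict: bool = False) -> StagePrediction:
    """Apply the geometric staging rule to binary masks.

    ``breach_voxel_count`` counts tumor voxels outside the rectum mask;
    any breach means >=T3, otherwise <=T2.  An empty tumor mask is
    (vacuously) <=T2 and flagged via ``tumor_empty``.  With
    ``contour_strict=True`` a tumor touching the outer rectum boundary
    from inside (face connectivity) also counts as a breach.
    """
    tumor = masks.tumor
    rectum = masks.rectum
    breach = int(np.count_nonzero(tumor & ~rectum))
    if contour_strict and breach == 0 and tumor.any():
        # Outer boundary of the rectum mask: rectum voxels with a face
        # neighbor outside the mask (or on the volume edge).
        interior = ndimage.binary_erosion(
            rectum, structure=ndimage.generate_binary_structure(3, 1), border_value=0
        )
        boundary = rectum & ~interior
        breach = int(np.count_nonzero(tumor & boundary))
    empty = not bool(tumor.any())
    category = StageCategory.GE_T3 if breach > 0 else StageCategory.LE_T2
    return StagePrediction(category=category, breach_voxel_count=breach, tumor_empty=empty)


def stage_prediction_to_label(pred: StagePrediction) -> StageLabel:
    """Collapse a prediction to a bare stage label (for confusion counts)."""
    return StageLabel(pred.category)
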