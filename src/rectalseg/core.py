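"""Shared domain types: voxel grids, label sets, probability maps, stages.

Conventions used throughout the package:

* Volumes are 3D arrays indexed ``[i, j, k]``; axis ``a`` has voxel size
  ``spacing_mm[a]`` and the physical coordinate of voxel ``(0, 0, 0)``'s
  center is ``origin_mm``.  Physical coordinates are in millimeters,
  voxel indices 0-based, voxel-center convention.
* Segmentation channels are ordered ``(tumor, rectum, mesorectum)``.
  The rectum mask covers everything inside the outer boundary of the
  muscularis propria (lumen + wall), so tumor and rectum legitimately
  overlap; a tumor voxel outside the rectum mask is a mural breach.
* The binary pathological stage is "<=T2" (tumor confined within the
  muscularis propria) versus ">=T3" (invasion into the mesorectum),
  encoded for training as g_staging = -1 / +1.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "ValidationError",
    "VolumeFormatError",
    "VoxelGrid",
    "SegLabels",
    "ProbMaps",
    "StageCategory",
    "StageLabel",
    "StagePrediction",
    "Case",
    "CHANNEL_ORDER",
]

CHANNEL_ORDER = ("tumor", "rectum", "mesorectum")


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class VolumeFormatError(ValueError):
    """A volume file is missing, corrupt, or has unexpected dimensionality."""


def _as_float_triple(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValidationError(f"expected 3 components, got {len(t)}")
    return t  # type: ignore[return-value]


@dataclass
class VoxelGrid:
    """A 3D scalar intensity volume with physical geometry.

    Parameters
    ----------
    values
        3D array of voxel intensities.
    spacing_mm
        Per-axis voxel size in mm; all components must be positive.
    origin_mm
        Physical coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise VolumeFormatError(
                f"VoxelGrid requires a 3D array, got ndim={self.values.ndim}"
            )
        if min(self.values.shape) < 1:
            raise ValidationError("all grid axes must have length >= 1")
        self.spacing_mm = _as_float_triple(self.spacing_mm)
        self.origin_mm = _as_float_triple(self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the volume (one voxel spans one spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))  # type: ignore[return-value]

    def voxel_to_physical(self, index) -> np.ndarray:
        return np.asarray(self.origin_mm) + np.asarray(index) * np.asarray(self.spacing_mm)

    def physical_to_voxel(self, coord_mm) -> np.ndarray:
        """Continuous voxel index of a physical coordinate."""
        return (np.asarray(coord_mm, dtype=float) - np.asarray(self.origin_mm)) / np.asarray(
            self.spacing_mm
        )

    def contains_physical(self, coord_mm) -> bool:
        """Whether a physical point falls inside the voxel lattice's extent."""
        idx = self.physical_to_voxel(coord_mm)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.asarray(self.shape) - 0.5))


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim != 3:
        raise ValidationError(f"{name} mask must be 3D, got ndim={arr.ndim}")
    if arr.dtype != np.bool_:
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValidationError(f"{name} mask must be binary, found values {uniq[:5]}")
        arr = arr.astype(bool)
    return arr


@dataclass
class SegLabels:
    """Three binary masks (tumor, rectum, mesorectum) on a shared grid."""

    tumor: np.ndarray
    rectum: np.ndarray
    mesorectum: np.ndarray

    def __post_init__(self) -> None:
        self.tumor = _check_binary(self.tumor, "tumor")
        self.rectum = _check_binary(self.rectum, "rectum")
        self.mesorectum = _check_binary(self.mesorectum, "mesorectum")
        if not (self.tumor.shape == self.rectum.shape == self.mesorectum.shape):
            raise ValidationError(
                "tumor/rectum/mesorectum masks must share one shape, got "
                f"{self.tumor.shape}/{self.rectum.shape}/{self.mesorectum.shape}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tumor.shape  # type: ignore[return-value]

    def stack(self) -> np.ndarray:
        """Channel-first array ``(3, *shape)`` in the package channel order."""
        return np.stack([self.tumor, self.rectum, self.mesorectum])

    @classmethod
    def from_stack(cls, arr: np.ndarray) -> "SegLabels":
        if arr.ndim != 4 or arr.shape[0] != 3:
            raise ValidationError(f"expected (3, D, H, W) stack, got {arr.shape}")
        return cls(tumor=arr[0], rectum=arr[1], mesorectum=arr[2])


@dataclass
class ProbMaps:
    """Per-voxel probabilities for the three structures, values in [0, 1]."""

    tumor: np.ndarray
    rectum: np.ndarray
    mesorectum: np.ndarray

    def __post_init__(self) -> None:
        for name in CHANNEL_ORDER:
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.ndim != 3:
                raise ValidationError(f"{name} probabilities must be 3D")
            if arr.size == 0:
                raise ValidationError(f"{name} probability map is empty")
            if arr.min() < 0.0 or arr.max() > 1.0:
                raise ValidationError(f"{name} probabilities outside [0, 1]")
            setattr(self, name, arr)
        if not (self.tumor.shape == self.rectum.shape == self.mesorectum.shape):
            raise ValidationError("probability channels must share one shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.tumor.shape  # type: ignore[return-value]

    def stack(self) -> np.ndarray:
        return np.stack([self.tumor, self.rectum, self.mesorectum])

    @classmethod
    def from_stack(cls, arr: np.ndarray) -> "ProbMaps":
        if arr.ndim != 4 or arr.shape[0] != 3:
            raise ValidationError(f"expected (3, D, H, W) stack, got {arr.shape}")
        return cls(tumor=arr[0], rectum=arr[1], mesorectum=arr[2])


class StageCategory(Enum):
    """Binary T stage: confined to the rectal wall vs mesorectal invasion."""

    LE_T2 = "<=T2"
    GE_T3 = ">=T3"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class StageLabel:
    """Ground-truth binary stage with its +/-1 training encoding."""

    category: StageCategory

    @property
    def g_staging(self) -> int:
        """+1 for >=T3, -1 for <=T2."""
        return 1 if self.category is StageCategory.GE_T3 else -1

    @classmethod
    def from_g(cls, g: int) -> "StageLabel":
        if g not in (-1, 1):
            raise ValidationError(f"g_staging must be -1 or +1, got {g}")
        return cls(StageCategory.GE_T3 if g == 1 else StageCategory.LE_T2)

    @classmethod
    def t2(cls) -> "StageLabel":
        return cls(StageCategory.LE_T2)

    @classmethod
    def t3(cls) -> "StageLabel":
        return cls(StageCategory.GE_T3)


@dataclass(frozen=True)
class StagePrediction:
    """Predicted binary stage derived from binarized masks.

    ``breach_voxel_count`` is the number of tumor voxels outside the rectum
    mask; the category is >=T3 exactly when it is positive.  ``tumor_empty``
    flags predictions whose tumor mask contained no voxel at all (vacuously
    classified <=T2, but worth surfacing as a failed segmentation).
    """

    category: StageCategory
    breach_voxel_count: int
    tumor_empty: bool = False

    def __post_init__(self) -> None:
        if (self.breach_voxel_count > 0) != (self.category is StageCategory.GE_T3):
            raise ValidationError(
                "category must be >=T3 exactly when breach_voxel_count > 0"
            )
        if self.breach_voxel_count < 0:
            raise ValidationError("breach_voxel_count must be >= 0")


@dataclass
class Case:
    """One subject: a volume, a tumor center, a stage, optional masks.

    Cases with ``labels`` carry full ground-truth segmentation; cases
    without are staging-only and contribute to training solely through the
    staging term of the loss.
    """

    volume: VoxelGrid
    center_mm: tuple[float, float, float]
    stage: StageLabel
    labels: Optional[SegLabels] = None
    case_id: str = "case"
    mucinous: bool = False

    def __post_init__(self) -> None:
        self.center_mm = _as_float_triple(self.center_mm)
        if self.labels is not None and self.labels.shape != self.volume.shape:
            raise ValidationError(
                f"label shape {self.labels.shape} does not match volume shape "
                f"{self.volume.shape}"
            )

    @property
    def has_labels(self) -> bool:
        return self.labels is not None
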