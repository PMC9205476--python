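"""Volume I/O (NIfTI) and the preprocessing chain.

Preprocessing mirrors a tumor-centered patch pipeline: resample the
acquisition to an isotropic voxel size (trilinear for intensities,
nearest-neighbor for masks), crop a fixed-size patch around the
user-supplied tumor center, and z-score the intensities.  Geometry is
tracked in physical millimeters with a voxel-center convention, so masks
and images stay aligned through every step.
"""

from __future__ import annotations

import os
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np
from scipy import ndimage

from .core import (
    Case,
    SegLabels,
    ValidationError,
    VolumeFormatError,
    VoxelGrid,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "resample_isotropic",
    "resample_labels",
    "crop_around",
    "crop_labels",
    "normalize_intensity",
    "preprocess_case",
    "DEFAULT_TARGET_MM",
    "DEFAULT_OUT_SHAPE",
]

#: Paper-scale preprocessing defaults: 0.5 mm isotropic, 256x256x128 patch.
DEFAULT_TARGET_MM = 0.5
DEFAULT_OUT_SHAPE = (256, 256, 128)


def _affine_from_grid(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing_mm)
    aff[:3, 3] = grid.origin_mm
    return aff


def read_volume(path: Union[str, os.PathLike]) -> VoxelGrid:
    """Read a 3D NIfTI volume into a :class:`VoxelGrid`."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise VolumeFormatError(f"volume file not found: {path}")
    try:
        img = nib.load(path)
        data = np.asarray(img.dataobj)
    except Exception as exc:  # corrupt file
        raise VolumeFormatError(f"cannot read volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D image, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VoxelGrid(np.asarray(data, dtype=np.float32), spacing, origin)


def write_volume(grid: VoxelGrid, path: Union[str, os.PathLike]) -> None:
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float32), _affine_from_grid(grid))
    img.header.set_zooms(grid.spacing_mm)
    nib.save(img, os.fspath(path))


def write_labels(labels: SegLabels, grid: VoxelGrid, path: Union[str, os.PathLike]) -> None:
    """Write the three masks as one 4D NIfTI (last axis = channel)."""
    stack = np.moveaxis(labels.stack().astype(np.uint8), 0, -1)
    img = nib.Nifti1Image(stack, _affine_from_grid(grid))
    nib.save(img, os.fspath(path))


def read_labels(path: Union[str, Sequence[Union[str, os.PathLike]]]) -> tuple[SegLabels, VoxelGrid]:
    """Read labels from a 4-channel file or three single-channel files.

    Returns the masks and a reference grid carrying their geometry (values
    are the tumor mask).
    """
    if isinstance(path, (str, os.PathLike)):
        p = os.fspath(path)
        if not os.path.exists(p):
            raise VolumeFormatError(f"label file not found: {p}")
        img = nib.load(p)
        data = np.asarray(img.dataobj)
        if data.ndim == 4 and data.shape[-1] == 3:
            stack = np.moveaxis(data, -1, 0)
        elif data.ndim == 3:
            raise VolumeFormatError(
                f"{p}: single 3D label file; pass the three per-structure files together"
            )
        else:
            raise VolumeFormatError(f"{p}: expected (X,Y,Z,3) labels, got shape {data.shape}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
    else:
        paths = [os.fspath(q) for q in path]
        if len(paths) != 3:
            raise VolumeFormatError("expected exactly three single-channel label files")
        grids = [read_volume(q) for q in paths]
        stack = np.stack([g.values for g in grids])
        spacing, origin = grids[0].spacing_mm, grids[0].origin_mm
    labels = SegLabels.from_stack(stack > 0.5)
    return labels, VoxelGrid(labels.tumor.astype(np.uint8), spacing, origin)


def _resample_values(
    values: np.ndarray,
    spacing: Sequence[float],
    target_mm: float,
    order: int,
) -> np.ndarray:
    """Resample one channel to isotropic spacing, voxel centers aligned at 0."""
    spacing = np.asarray(spacing, dtype=float)
    out_shape = np.maximum(
        1, np.round(np.asarray(values.shape) * spacing / target_mm).astype(int)
    )
    scale = target_mm / spacing  # input index per output index
    if np.allclose(scale, 1.0) and tuple(out_shape) == values.shape:
        return values.copy()
    return ndimage.affine_transform(
        np.asarray(values, dtype=np.float32 if order > 0 else values.dtype),
        np.diag(scale),
        offset=0.0,
        output_shape=tuple(out_shape),
        order=order,
        mode="nearest",
    )


def resample_isotropic(grid: VoxelGrid, target_mm: float, order: int = 1) -> VoxelGrid:
    """Resample a grid to ``target_mm`` isotropic voxels (trilinear).

    The physical extent is preserved within one voxel; voxel (0,0,0)
    keeps its physical position (the origin is unchanged).
    """
    if target_mm <= 0:
        raise ValidationError(f"target_mm must be positive, got {target_mm}")
    values = _resample_values(grid.values, grid.spacing_mm, target_mm, order)
    return VoxelGrid(values, (target_mm,) * 3, grid.origin_mm)


def resample_labels(labels: SegLabels, spacing_mm: Sequence[float], target_mm: float) -> SegLabels:
    """Nearest-neighbor resampling of the three masks."""
    if target_mm <= 0:
        raise ValidationError(f"target_mm must be positive, got {target_mm}")
    chans = [
        _resample_values(m.astype(np.uint8), spacing_mm, target_mm, order=0)
        for m in (labels.tumor, labels.rectum, labels.mesorectum)
    ]
    return SegLabels.from_stack(np.stack(chans) > 0)


def _crop_window(grid_shape, spacing, origin, center_mm, out_shape):
    center_idx = np.round(
        (np.asarray(center_mm, dtype=float) - np.asarray(origin)) / np.asarray(spacing)
    ).astype(int)
    out_shape = np.asarray(out_shape, dtype=int)
    start = center_idx - out_shape // 2
    return start, out_shape


def crop_around(
    grid: VoxelGrid,
    center_mm: Sequence[float],
    out_shape: Sequence[int],
    pad_value: Optional[float] = None,
) -> VoxelGrid:
    """Crop a fixed-size patch so ``center_mm`` lands on the central voxel.

    Regions outside the input are padded with ``pad_value`` (default: the
    input's minimum intensity, which avoids bright-border artifacts on
    MR-like data).
    """
    out_shape = tuple(int(n) for n in out_shape)
    if min(out_shape) < 1:
        raise ValidationError(f"out_shape components must be >= 1, got {out_shape}")
    if not grid.contains_physical(center_mm):
        raise ValidationError(
            f"center {tuple(center_mm)} mm lies outside the volume extent"
        )
    start, out = _crop_window(grid.shape, grid.spacing_mm, grid.origin_mm, center_mm, out_shape)
    if pad_value is None:
        pad_value = float(grid.values.min())
    dest = np.full(out_shape, pad_value, dtype=grid.values.dtype)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + out, grid.shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + np.maximum(src_hi - src_lo, 0)
    if np.all(src_hi > src_lo):
        dest[tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))] = grid.values[
            tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
        ]
    new_origin = tuple(
        o + s * sp for o, s, sp in zip(grid.origin_mm, start, grid.spacing_mm)
    )
    return VoxelGrid(dest, grid.spacing_mm, new_origin)


def crop_labels(
    labels: SegLabels,
    grid: VoxelGrid,
    center_mm: Sequence[float],
    out_shape: Sequence[int],
) -> SegLabels:
    """Crop masks with the exact geometry used for the intensity crop."""
    chans = []
    for m in (labels.tumor, labels.rectum, labels.mesorectum):
        g = VoxelGrid(m.astype(np.uint8), grid.spacing_mm, grid.origin_mm)
        chans.append(crop_around(g, center_mm, out_shape, pad_value=0).values)
    return SegLabels.from_stack(np.stack(chans) > 0)


def normalize_intensity(grid: VoxelGrid) -> VoxelGrid:
    """Z-score the volume: zero mean, unit variance (constant input -> zeros)."""
    values = np.asarray(grid.values, dtype=np.float32)
    if values.size == 0:
        raise ValidationError("cannot normalize an empty volume")
    sd = float(values.std())
    if sd == 0.0:
        out = np.zeros_like(values)
    else:
        out = (values - float(values.mean())) / sd
    return VoxelGrid(out, grid.spacing_mm, grid.origin_mm)


def preprocess_case(
    case: Case,
    target_mm: float = DEFAULT_TARGET_MM,
    out_shape: Sequence[int] = DEFAULT_OUT_SHAPE,
) -> tuple[VoxelGrid, Optional[SegLabels]]:
    """Resample -> tumor-centered crop -> z-score, labels tracked alongside.

    Masks are resampled nearest-neighbor and cropped with identical
    geometry but never normalized.  Staging-only cases return ``None``
    for the labels.
    """
    iso = resample_isotropic(case.volume, target_mm, order=1)
    patch = crop_around(iso, case.center_mm, out_shape)
    patch = normalize_intensity(patch)
    labels_out: Optional[SegLabels] = None
    if case.labels is not None:
        iso_labels = resample_labels(case.labels, case.volume.spacing_mm, target_mm)
        ref = VoxelGrid(iso_labels.tumor.astype(np.uint8), iso.spacing_mm, iso.origin_mm)
        labels_out = crop_labels(iso_labels, ref, case.center_mm, out_shape)
    return patch, labels_out
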