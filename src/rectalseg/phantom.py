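"""Synthetic rectal-anatomy phantoms with ground-truth labels and stages.

The phantom is a nested tubular geometry mimicking a high-resolution
T2-weighted pelvic MR acquisition around the rectum:

* a dark **lumen** along the tube axis,
* the **rectal wall** (muscularis propria), low signal,
* the **mesorectum**, a fat envelope with high T2 signal,
* a **tumor** occupying an angular sector of the wall, intermediate
  signal (or high signal for the mucinous variant, which makes it nearly
  isointense with fat and correspondingly hard to segment).

The rectum label covers everything within the outer boundary of the
muscularis propria (lumen + wall), so a tumor confined to the wall is a
subset of the rectum label (stage <=T2) while a tumor extending radially
past the outer wall boundary acquires voxels in the mesorectum (stage
>=T3).  The stage is always derived from the generated voxel masks, never
stored independently, so label and geometry cannot drift apart.

Noise is Rician: the magnitude of the noiseless signal plus complex
Gaussian noise, the standard statistics of magnitude MR images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import Case, SegLabels, StageLabel, ValidationError, VoxelGrid

__all__ = [
    "PhantomSpec",
    "CohortRanges",
    "DEFAULT_INTENSITY_MEANS",
    "generate_phantom",
    "generate_cohort",
]

logger = logging.getLogger(__name__)

#: Noiseless per-tissue mean signals (arbitrary units). The mucinous tumor
#: mean sits close to mesorectal fat, emulating the near-isointense
#: appearance of mucin pools on T2-weighted images.
DEFAULT_INTENSITY_MEANS: Mapping[str, float] = {
    "background": 45.0,
    "lumen": 20.0,
    "wall": 60.0,
    "mesorectum": 165.0,
    "tumor": 110.0,
    "tumor_mucinous": 175.0,
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic case.

    ``invasion_depth_mm`` controls the stage: values <= 0 keep the tumor
    strictly inside the outer wall boundary (<=T2); positive values push
    the tumor cap ``invasion_depth_mm`` beyond it into the mesorectum
    (>=T3).  The default grid is anisotropic (0.5 mm in-plane, 3.5 mm
    effective slice pitch: 3 mm slices + 0.5 mm gap) so that isotropic
    resampling downstream is genuinely exercised.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 24)
    spacing_mm: tuple[float, float, float] = (0.5, 0.5, 3.5)
    lumen_radius_mm: float = 4.0
    wall_thickness_mm: float = 3.0
    mesorectum_radius_mm: float = 16.0
    tube_axis: int = 2
    curvature_amp_mm: float = 0.0
    tumor_angular_extent_deg: float = 120.0
    tumor_theta0_deg: float = 0.0
    tumor_length_mm: float = 30.0
    invasion_depth_mm: float = -1.5
    mucinous: bool = False
    intensity_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY_MEANS)
    )
    noise_sigma: float = 8.0
    seed: int = 0

    @property
    def outer_wall_radius_mm(self) -> float:
        return self.lumen_radius_mm + self.wall_thickness_mm

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or min(self.grid_shape) < 1:
            raise ValidationError(f"grid_shape must be three positive ints: {self.grid_shape}")
        if min(self.spacing_mm) <= 0:
            raise ValidationError(f"spacing must be positive: {self.spacing_mm}")
        if not (0 < self.lumen_radius_mm < self.outer_wall_radius_mm < self.mesorectum_radius_mm):
            raise ValidationError(
                "radii must satisfy 0 < lumen < lumen+wall < mesorectum, got "
                f"{self.lumen_radius_mm}, {self.outer_wall_radius_mm}, "
                f"{self.mesorectum_radius_mm}"
            )
        if self.tube_axis not in (0, 1, 2):
            raise ValidationError(f"tube_axis must be 0, 1 or 2, got {self.tube_axis}")
        if not (0.0 < self.tumor_angular_extent_deg <= 360.0):
            raise ValidationError(
                f"tumor_angular_extent_deg must be in (0, 360], got {self.tumor_angular_extent_deg}"
            )
        if self.tumor_length_mm <= 0:
            raise ValidationError("tumor_length_mm must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.invasion_depth_mm >= self.mesorectum_radius_mm - self.outer_wall_radius_mm:
            raise ValidationError(
                "invasion_depth_mm must leave the tumor inside the mesorectum envelope"
            )
        missing = {"background", "lumen", "wall", "mesorectum", "tumor"} - set(
            self.intensity_means
        )
        if missing:
            raise ValidationError(f"intensity_means missing tissues: {sorted(missing)}")


def _phantom_geometry(spec: PhantomSpec):
    """Radial distance, angle and along-axis coordinate for every voxel."""
    shape = spec.grid_shape
    axes = [np.arange(n) * s for n, s in zip(shape, spec.spacing_mm)]
    ax = spec.tube_axis
    trans = [a for a in range(3) if a != ax]

    coords = np.meshgrid(*axes, indexing="ij")
    z = coords[ax]
    # Tube centerline: in-plane center of the volume, optionally displaced
    # sinusoidally along the first transverse axis (gentle curvature).
    centers = [(shape[a] - 1) * spec.spacing_mm[a] / 2.0 for a in range(3)]
    z_len = max(shape[ax] * spec.spacing_mm[ax], 1e-9)
    c1 = centers[trans[0]] + spec.curvature_amp_mm * np.sin(2.0 * np.pi * z / z_len)
    c2 = centers[trans[1]]
    d1 = coords[trans[0]] - c1
    d2 = coords[trans[1]] - c2
    r = np.hypot(d1, d2)
    theta = np.degrees(np.arctan2(d2, d1))  # (-180, 180]
    return r, theta, z, centers


def generate_phantom(spec: PhantomSpec) -> Case:
    """Render one synthetic case (volume + labels + stage) from a spec.

    Deterministic for a fixed ``spec.seed``.  The returned stage is
    computed from the voxel masks: >=T3 exactly when at least one tumor
    voxel falls outside the rectum mask.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    r, theta, z, centers = _phantom_geometry(spec)
    r_wall = spec.outer_wall_radius_mm

    lumen = r < spec.lumen_radius_mm
    rectum = r < r_wall  # everything within the muscularis propria
    mesorectum = (r >= r_wall) & (r < spec.mesorectum_radius_mm)

    # Tumor: an angular-sector thickening of the wall with a smooth cap in
    # (angle, length) so its radial extent tapers to zero at the margins.
    z_center = centers[spec.tube_axis]
    d_theta = (theta - spec.tumor_theta0_deg + 180.0) % 360.0 - 180.0
    u = d_theta / (spec.tumor_angular_extent_deg / 2.0)
    v = (z - z_center) / (spec.tumor_length_mm / 2.0)
    cap = np.clip(1.0 - u * u, 0.0, 1.0) * np.clip(1.0 - v * v, 0.0, 1.0)
    r_outer = r_wall + spec.invasion_depth_mm * np.sqrt(cap)
    tumor = (cap > 0.05) & (r >= 0.5 * spec.lumen_radius_mm) & (r < r_outer)
    tumor &= r < spec.mesorectum_radius_mm  # safety: stay inside the envelope

    if not tumor.any():
        raise ValidationError(
            "spec produced an empty tumor mask; increase tumor extent or grid resolution"
        )

    means = spec.intensity_means
    volume = np.full(spec.grid_shape, float(means["background"]), dtype=np.float32)
    volume[mesorectum] = means["mesorectum"]
    volume[rectum] = means["wall"]
    volume[lumen] = means["lumen"]
    tumor_mean = means.get("tumor_mucinous", means["tumor"]) if spec.mucinous else means["tumor"]
    volume[tumor] = tumor_mean

    if spec.noise_sigma > 0:
        n1 = rng.normal(0.0, spec.noise_sigma, size=volume.shape)
        n2 = rng.normal(0.0, spec.noise_sigma, size=volume.shape)
        volume = np.hypot(volume + n1, n2).astype(np.float32)

    labels = SegLabels(tumor=tumor, rectum=rectum, mesorectum=mesorectum)
    breach = int(np.count_nonzero(tumor & ~rectum))
    stage = StageLabel.t3() if breach > 0 else StageLabel.t2()

    center_idx = np.argwhere(tumor).mean(axis=0)
    center_mm = tuple(center_idx * np.asarray(spec.spacing_mm))

    return Case(
        volume=VoxelGrid(volume, spec.spacing_mm),
        center_mm=center_mm,  # type: ignore[arg-type]
        stage=stage,
        labels=labels,
        case_id=f"phantom_seed{spec.seed}",
        mucinous=spec.mucinous,
    )


def _check_range(name: str, rg: Sequence[float]) -> tuple[float, float]:
    lo, hi = float(rg[0]), float(rg[1])
    if hi < lo:
        raise ValidationError(f"empty range for {name}: ({lo}, {hi})")
    return lo, hi


@dataclass
class CohortRanges:
    """Per-case parameter ranges for cohort synthesis (uniform draws)."""

    lumen_radius_mm: tuple[float, float] = (3.0, 5.0)
    wall_thickness_mm: tuple[float, float] = (2.5, 3.5)
    mesorectum_radius_mm: tuple[float, float] = (14.0, 18.0)
    curvature_amp_mm: tuple[float, float] = (0.0, 2.0)
    tumor_angular_extent_deg: tuple[float, float] = (80.0, 180.0)
    tumor_theta0_deg: tuple[float, float] = (0.0, 360.0)
    tumor_length_mm: tuple[float, float] = (20.0, 40.0)
    invasion_depth_t2_mm: tuple[float, float] = (-2.5, -0.75)
    invasion_depth_t3_mm: tuple[float, float] = (1.5, 4.0)
    noise_sigma: tuple[float, float] = (6.0, 10.0)

    def validate(self) -> None:
        for name in self.__dataclass_fields__:
            _check_range(name, getattr(self, name))
        if self.invasion_depth_t2_mm[1] > 0:
            raise ValidationError("invasion_depth_t2_mm must be <= 0 (confined tumor)")
        if self.invasion_depth_t3_mm[0] <= 0:
            raise ValidationError("invasion_depth_t3_mm must be > 0 (mesorectal breach)")


def generate_cohort(
    n: int,
    t3_fraction: float = 119 / 201,
    seg_labeled_fraction: float = 135 / 201,
    mucinous_fraction: float = 6 / 201,
    spec_ranges: Optional[CohortRanges] = None,
    base_spec: Optional[PhantomSpec] = None,
    seed: int = 0,
) -> list[Case]:
    """Draw a reproducible synthetic cohort of cases.

    Exactly ``round(n * seg_labeled_fraction)`` cases keep their
    segmentation labels (the rest are staging-only), ``round(n *
    t3_fraction)`` cases are generated with mesorectal invasion and
    ``round(n * mucinous_fraction)`` with the mucinous intensity profile.
    The fraction defaults mirror a 201-case cohort with 135 labeled cases
    and 119 >=T3 cases.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    for name, frac in (
        ("t3_fraction", t3_fraction),
        ("seg_labeled_fraction", seg_labeled_fraction),
        ("mucinous_fraction", mucinous_fraction),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {frac}")
    ranges = spec_ranges or CohortRanges()
    ranges.validate()
    base = base_spec or PhantomSpec()

    rng = np.random.default_rng(seed)
    n_t3 = int(round(n * t3_fraction))
    n_lab = int(round(n * seg_labeled_fraction))
    n_muc = int(round(n * mucinous_fraction))

    is_t3 = np.zeros(n, dtype=bool)
    is_t3[rng.permutation(n)[:n_t3]] = True
    has_labels = np.zeros(n, dtype=bool)
    has_labels[rng.permutation(n)[:n_lab]] = True
    is_muc = np.zeros(n, dtype=bool)
    is_muc[rng.permutation(n)[:n_muc]] = True

    def draw(rg: tuple[float, float]) -> float:
        lo, hi = rg
        return float(rng.uniform(lo, hi)) if hi > lo else lo

    cases: list[Case] = []
    for i in range(n):
        inv_range = ranges.invasion_depth_t3_mm if is_t3[i] else ranges.invasion_depth_t2_mm
        spec = replace(
            base,
            lumen_radius_mm=draw(ranges.lumen_radius_mm),
            wall_thickness_mm=draw(ranges.wall_thickness_mm),
            mesorectum_radius_mm=draw(ranges.mesorectum_radius_mm),
            curvature_amp_mm=draw(ranges.curvature_amp_mm),
            tumor_angular_extent_deg=draw(ranges.tumor_angular_extent_deg),
            tumor_theta0_deg=draw(ranges.tumor_theta0_deg),
            tumor_length_mm=draw(ranges.tumor_length_mm),
            invasion_depth_mm=draw(inv_range),
            noise_sigma=draw(ranges.noise_sigma),
            mucinous=bool(is_muc[i]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        case = generate_phantom(spec)
        case.case_id = f"case_{i:04d}"
        if not has_labels[i]:
            case.labels = None
        want = StageLabel.t3() if is_t3[i] else StageLabel.t2()
        if case.stage != want:  # pragma: no cover - guarded by range validation
            logger.warning(
                "case %s: drawn geometry produced stage %s (intended %s); "
                "keeping the geometry-derived stage",
                case.case_id,
                case.stage.category,
                want.category,
            )
        cases.append(case)
    return cases
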