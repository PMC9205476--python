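"""Training loop, augmentation, mixed batches and 10-fold cross-validation.

Protocol implemented here:

* every batch mixes 3 segmentation-labeled cases with 2 staging-only
  cases (batch size 5); staging-only cases contribute only the staging
  term of the loss;
* Adam (lr 0.003, beta1 0.9, beta2 0.999, eps 1e-8) minimizes
  ``Loss_SEG + lambda * Loss_STG`` with lambda 0.02 by default;
* the validation set is scored every 100 iterations and the checkpoint
  maximizing (mean DSC + staging sensitivity + staging specificity) is
  kept;
* 10-fold cross-validation rotates fold roles: rotation ``r`` evaluates
  on fold ``r``, validates on fold ``(r+1) mod k`` and trains on the
  remaining eight folds, so every case is evaluated exactly once.

All randomness flows from a single master seed split into named
substreams (fold assignment, weight init, batch sampling, augmentation).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterator, Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import Case, ProbMaps, SegLabels, StageLabel, StagePrediction, ValidationError, VoxelGrid
from .io_volumes import preprocess_case
from .losses import LossConfig, combined_loss_grad
from .metrics import (
    ConfusionTable2x2,
    DscSummary,
    accuracy,
    dsc,
    sensitivity,
    specificity,
    staging_confusion,
    summarize_dsc,
)
from .nn import Adam, NetworkConfig, UNet3D, build_network
from .staging import binarize, classify_stage

__all__ = [
    "AugmentRanges",
    "TrainConfig",
    "TrainedModel",
    "FoldSplit",
    "CVReport",
    "augment",
    "make_batches",
    "make_fold_split",
    "train",
    "cross_validate",
    "predict_case",
    "evaluate_cases",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


@dataclass
class AugmentRanges:
    """Uniform draw ranges for per-sample training augmentation.

    ``scale`` rescales the anatomy physically (spacing and coordinates);
    ``rotation_deg`` rotates in the plane perpendicular to the
    through-plane axis; ``slice_thickness_mm`` resamples the
    through-plane axis to a random thickness before the isotropic
    preprocessing resample.
    """

    scale: tuple[float, float] = (0.9, 1.1)
    rotation_deg: tuple[float, float] = (-10.0, 10.0)
    slice_thickness_mm: tuple[float, float] = (2.0, 4.0)

    def validate(self) -> None:
        for name in ("scale", "rotation_deg", "slice_thickness_mm"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValidationError(f"degenerate augmentation range {name}: ({lo}, {hi})")
        if self.scale[0] <= 0:
            raise ValidationError("scale must stay positive")
        if self.slice_thickness_mm[0] <= 0:
            raise ValidationError("slice thickness must stay positive")


def _through_plane_axis(spacing: Sequence[float]) -> int:
    return int(np.argmax(spacing))


def _rotate_inplane(values: np.ndarray, angle_deg: float, axes: tuple[int, int], order: int):
    """Rotate content by ``angle_deg`` in the (axes) plane about the array center."""
    theta = math.radians(angle_deg)
    rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
    mat = np.eye(3)
    a1, a2 = axes
    mat[np.ix_([a1, a2], [a1, a2])] = rot.T  # inverse mapping: output -> input
    center = (np.asarray(values.shape) - 1) / 2.0
    offset = center - mat @ center
    return ndimage.affine_transform(
        values, mat, offset=offset, order=order, mode="nearest", output=values.dtype
    )


def augment(case: Case, ranges: AugmentRanges, seed) -> Case:
    """Scale / rotate / slice-thickness-convert one case, labels in lockstep.

    The stage label is untouched (similarity transforms preserve the
    breach topology); masks use nearest-neighbor interpolation; the tumor
    center coordinate is carried through the same geometry.  ``seed`` may
    be an int or a ``numpy.random.Generator``.
    """
    ranges.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = float(rng.uniform(*ranges.scale))
    angle = float(rng.uniform(*ranges.rotation_deg))
    thickness = float(rng.uniform(*ranges.slice_thickness_mm))

    grid = case.volume
    spacing = np.asarray(grid.spacing_mm, dtype=float)
    origin = np.asarray(grid.origin_mm, dtype=float)
    center = np.asarray(case.center_mm, dtype=float)
    values = np.asarray(grid.values, dtype=np.float32)
    labels = case.labels.stack().astype(np.uint8) if case.labels is not None else None

    axis = _through_plane_axis(spacing)
    inplane = tuple(a for a in range(3) if a != axis)

    # 1) in-plane rotation about the volume's physical center
    if angle != 0.0:
        if not math.isclose(spacing[inplane[0]], spacing[inplane[1]], rel_tol=1e-6):
            raise ValidationError("in-plane rotation requires equal in-plane spacing")
        values = _rotate_inplane(values, angle, inplane, order=1)
        if labels is not None:
            labels = np.stack([_rotate_inplane(c, angle, inplane, order=0) for c in labels])
        c_phys = origin + (np.asarray(values.shape) - 1) / 2.0 * spacing
        theta = math.radians(angle)
        rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        d = center[list(inplane)] - c_phys[list(inplane)]
        center = center.copy()
        center[list(inplane)] = c_phys[list(inplane)] + rot @ d

    # 2) slice thickness conversion along the through-plane axis
    if not math.isclose(thickness, spacing[axis], rel_tol=1e-9):
        zoom = spacing[axis] / thickness
        n_new = max(1, int(round(values.shape[axis] * zoom)))
        mat = np.ones(3)
        mat[axis] = thickness / spacing[axis]
        out_shape = list(values.shape)
        out_shape[axis] = n_new
        values = ndimage.affine_transform(
            values, np.diag(mat), order=1, mode="nearest", output_shape=tuple(out_shape)
        )
        if labels is not None:
            labels = np.stack(
                [
                    ndimage.affine_transform(
                        c, np.diag(mat), order=0, mode="nearest", output_shape=tuple(out_shape)
                    )
                    for c in labels
                ]
            )
        spacing = spacing.copy()
        spacing[axis] = thickness

    # 3) physical scaling: pure metadata change, no interpolation
    if scale != 1.0:
        spacing = spacing * scale
        origin = origin * scale
        center = center * scale

    new_labels = SegLabels.from_stack(labels > 0) if labels is not None else None
    return Case(
        volume=VoxelGrid(values, tuple(spacing), tuple(origin)),
        center_mm=tuple(center),
        stage=case.stage,
        labels=new_labels,
        case_id=case.case_id,
        mucinous=case.mucinous,
    )


# ---------------------------------------------------------------------------
# configuration / batches
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the studied protocol)."""

    learning_rate: float = 0.003
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_seg_cases: int = 3
    batch_staging_only_cases: int = 2
    max_iterations: int = 1000
    validate_every: int = 100
    loss: LossConfig = field(default_factory=LossConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    target_mm: float = 0.5
    out_shape: tuple[int, int, int] = (256, 256, 128)
    threshold: float = 0.5
    augment_ranges: Optional[AugmentRanges] = field(default_factory=AugmentRanges)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.validate_every < 1:
            raise ValidationError("validate_every must be >= 1")
        if self.batch_seg_cases < 0 or self.batch_staging_only_cases < 0:
            raise ValidationError("batch composition counts must be >= 0")
        if self.batch_seg_cases + self.batch_staging_only_cases < 1:
            raise ValidationError("batch size must be >= 1")

    @property
    def batch_size(self) -> int:
        return self.batch_seg_cases + self.batch_staging_only_cases


def make_batches(
    cases: Sequence[Case], cfg: TrainConfig, seed
) -> Iterator[list[int]]:
    """Yield index batches of ``batch_seg_cases`` labeled + the rest staging-only.

    Sampling is with replacement across batches (each batch draws its
    members uniformly from the respective pools) and reproducible from
    ``seed``.  If no staging-only case exists, batches fall back to
    all-labeled with a logged warning (and vice versa).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labeled = [i for i, c in enumerate(cases) if c.has_labels]
    staging_only = [i for i, c in enumerate(cases) if not c.has_labels]
    n_seg, n_stg = cfg.batch_seg_cases, cfg.batch_staging_only_cases
    if not labeled and n_seg > 0:
        raise ValidationError("no segmentation-labeled training cases available")
    if not staging_only and n_stg > 0:
        logger.warning(
            "no staging-only cases: falling back to batches of %d labeled cases",
            n_seg + n_stg,
        )
        n_seg, n_stg = n_seg + n_stg, 0
    while True:
        batch = [int(i) for i in rng.choice(labeled, size=n_seg)] if n_seg else []
        if n_stg:
            batch += [int(i) for i in rng.choice(staging_only, size=n_stg)]
        yield batch


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A trained network plus the preprocessing geometry it expects."""

    net: UNet3D
    target_mm: float
    out_shape: tuple[int, int, int]
    threshold: float = 0.5

    def predict(self, case: Case) -> tuple[SegLabels, StagePrediction]:
        return predict_case(self, case)


def _case_tensors(case: Case, cfg: TrainConfig) -> tuple[np.ndarray, Optional[np.ndarray]]:
    vol, labels = preprocess_case(case, cfg.target_mm, cfg.out_shape)
    x = np.asarray(vol.values, dtype=np.float32)[None]
    g = labels.stack().astype(np.float32) if labels is not None else None
    return x, g


def predict_case(
    model: TrainedModel, case: Case, threshold: Optional[float] = None
) -> tuple[SegLabels, StagePrediction]:
    """Preprocess -> forward -> binarize -> stage for one case.

    The returned masks live on the preprocessed (isotropic, cropped)
    grid; that grid's spacing/origin are enough to map back to the
    native volume.
    """
    thr = model.threshold if threshold is None else threshold
    vol, _ = preprocess_case(case, model.target_mm, model.out_shape)
    probs = model.net.forward(
        np.asarray(vol.values, dtype=np.float32)[None, None], training=False
    )[0]
    p_maps = ProbMaps.from_stack(np.clip(probs.astype(np.float64), 0.0, 1.0))
    masks = binarize(p_maps, thr)
    return masks, classify_stage(masks)


@dataclass
class ValidationRecord:
    iteration: int
    mean_dsc: float
    sensitivity: float
    specificity: float
    score: float


def _validation_score(
    net: UNet3D,
    tensors: list[tuple[np.ndarray, Optional[np.ndarray], StageLabel]],
    threshold: float,
) -> tuple[float, float, float, float]:
    dscs: list[float] = []
    preds: list[StagePrediction] = []
    truths: list[StageLabel] = []
    for x, g, stage in tensors:
        probs = net.forward(x[None], training=False)[0]
        masks = binarize(ProbMaps.from_stack(np.clip(probs.astype(np.float64), 0, 1)), threshold)
        preds.append(classify_stage(masks))
        truths.append(stage)
        if g is not None:
            stack = masks.stack()
            dscs.append(float(np.mean([dsc(stack[c], g[c] > 0.5) for c in range(3)])))
    table = staging_confusion(preds, truths)
    sens, spec = sensitivity(table), specificity(table)
    mean_dsc = float(np.mean(dscs)) if dscs else math.nan
    # NaN components (e.g. a one-class validation fold) contribute zero.
    score = sum(0.0 if math.isnan(v) else v for v in (mean_dsc, sens, spec))
    return mean_dsc, sens, spec, score


def train(
    train_cases: Sequence[Case],
    val_cases: Sequence[Case],
    cfg: TrainConfig,
) -> tuple[TrainedModel, dict]:
    """Minimize the combined loss; return the best-validation checkpoint.

    The history dict carries per-iteration loss terms and one record per
    validation pass; the returned model holds the parameters of the
    validation checkpoint maximizing mean DSC + sensitivity + specificity.
    """
    if not train_cases or not val_cases:
        raise ValidationError("training and validation case lists must be nonempty")
    ss = np.random.SeedSequence(cfg.seed)
    seed_init, seed_batch, seed_aug = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3))

    net = build_network(cfg.network, seed=seed_init)
    adam = Adam(net.named_params(), cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.epsilon)
    batch_iter = make_batches(train_cases, cfg, seed_batch)
    aug_rng = np.random.default_rng(seed_aug)

    # Static (non-augmented) tensors are reusable across iterations.
    cache: dict[int, tuple[np.ndarray, Optional[np.ndarray]]] = {}

    def tensors_for(idx: int) -> tuple[np.ndarray, Optional[np.ndarray]]:
        if cfg.augment_ranges is not None:
            aug = augment(train_cases[idx], cfg.augment_ranges, aug_rng)
            return _case_tensors(aug, cfg)
        if idx not in cache:
            cache[idx] = _case_tensors(train_cases[idx], cfg)
        return cache[idx]

    val_tensors = [(*_case_tensors(c, cfg), c.stage) for c in val_cases]

    history: dict = {"loss": [], "loss_seg": [], "loss_stg": [], "validation": []}
    best_score, best_state, best_iter = -math.inf, None, None

    for it in range(1, cfg.max_iterations + 1):
        batch = next(batch_iter)
        xs, gs = zip(*(tensors_for(i) for i in batch))
        x = np.stack(xs)
        probs = net.forward(x, training=True)
        gprobs = np.zeros_like(probs)
        loss_terms = np.zeros(2)
        for b, idx in enumerate(batch):
            case = train_cases[idx]
            labels = SegLabels.from_stack(gs[b] > 0.5) if gs[b] is not None else None
            value, grad = combined_loss_grad(probs[b], labels, case.stage, cfg.loss)
            seg_part = value - (
                cfg.loss.lam
                * _staging_term(probs[b], case.stage)
                if cfg.loss.staging_enabled and cfg.loss.lam > 0
                else 0.0
            )
            loss_terms += (seg_part, value - seg_part)
            gprobs[b] = grad / len(batch)
        loss = float(loss_terms.sum()) / len(batch)
        if not math.isfinite(loss):
            raise FloatingPointError(f"training loss diverged at iteration {it}: {loss}")
        net.backward(gprobs)
        adam.step(net.named_grads())
        history["loss"].append(loss)
        history["loss_seg"].append(float(loss_terms[0]) / len(batch))
        history["loss_stg"].append(float(loss_terms[1]) / len(batch))

        if it % cfg.validate_every == 0:
            mean_dsc, sens, spec, score = _validation_score(net, val_tensors, cfg.threshold)
            rec = ValidationRecord(it, mean_dsc, sens, spec, score)
            history["validation"].append(rec)
            logger.info(
                "iter %d: loss %.4f | val DSC %.3f sens %.3f spec %.3f",
                it, loss, mean_dsc, sens, spec,
            )
            if score > best_score:
                best_score, best_state, best_iter = score, net.state_dict(), it

    if best_state is not None:
        net.load_state_dict(best_state)
    history["selected_iteration"] = best_iter
    model = TrainedModel(net, cfg.target_mm, tuple(cfg.out_shape), cfg.threshold)
    return model, history


def _staging_term(p_stack: np.ndarray, stage: StageLabel) -> float:
    from .losses import staging_loss, staging_probability_argmax

    p_stg, _ = staging_probability_argmax(p_stack[0], p_stack[1])
    return staging_loss(p_stg, stage)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


@dataclass
class FoldSplit:
    """Fold membership and the per-rotation role assignment."""

    k: int
    folds: list[list[int]]

    def rotation(self, r: int) -> tuple[list[int], list[int], list[int]]:
        """(train, validation, evaluation) case indices for rotation ``r``."""
        eval_fold = self.folds[r]
        val_fold = self.folds[(r + 1) % self.k]
        train_idx = [
            i for f in range(self.k) if f not in (r, (r + 1) % self.k) for i in self.folds[f]
        ]
        return train_idx, list(val_fold), list(eval_fold)


def make_fold_split(n: int, k: int, seed) -> FoldSplit:
    """Seeded random partition of ``n`` cases into ``k`` folds."""
    if n < k:
        raise ValidationError(f"need at least k={k} cases, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = [sorted(int(i) for i in part) for part in np.array_split(perm, k)]
    if any(len(f) == 0 for f in folds):
        raise ValidationError("a fold received zero cases")
    return FoldSplit(k=k, folds=folds)


@dataclass
class CVReport:
    """Pooled and per-rotation cross-validation results."""

    k: int
    seed: int
    folds: list[list[int]]
    per_rotation: list[dict]
    pooled_confusion: ConfusionTable2x2
    pooled_sensitivity: float
    pooled_specificity: float
    pooled_accuracy: float
    dsc_summaries: dict[str, DscSummary]
    per_case: list[dict]

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "folds": self.folds,
            "per_rotation": self.per_rotation,
            "pooled_confusion": {
                "tp": self.pooled_confusion.tp,
                "fp": self.pooled_confusion.fp,
                "fn": self.pooled_confusion.fn,
                "tn": self.pooled_confusion.tn,
            },
            "pooled_sensitivity": self.pooled_sensitivity,
            "pooled_specificity": self.pooled_specificity,
            "pooled_accuracy": self.pooled_accuracy,
            "dsc_summaries": {
                s: {"median": d.median, "iqr": list(d.iqr), "n": len(d.values)}
                for s, d in self.dsc_summaries.items()
            },
            "per_case": self.per_case,
        }


def evaluate_cases(
    model, cases: Sequence[Case], cfg: TrainConfig
) -> tuple[list[dict], ConfusionTable2x2]:
    """Per-case DSC (labeled cases only) and staging outcomes for a model."""
    records: list[dict] = []
    preds: list[StagePrediction] = []
    truths: list[StageLabel] = []
    for case in cases:
        masks, pred = model.predict(case)
        preds.append(pred)
        truths.append(case.stage)
        rec: dict = {
            "case_id": case.case_id,
            "stage_true": case.stage.category.value,
            "stage_pred": pred.category.value,
            "breach_voxels": pred.breach_voxel_count,
            "tumor_empty": pred.tumor_empty,
        }
        if case.has_labels:
            _, truth = preprocess_case(case, cfg.target_mm, cfg.out_shape)
            pred_stack, truth_stack = masks.stack(), truth.stack()
            for c, name in enumerate(("tumor", "rectum", "mesorectum")):
                rec[f"dsc_{name}"] = dsc(pred_stack[c], truth_stack[c])
        records.append(rec)
    return records, staging_confusion(preds, truths)


Trainer = Callable[[Sequence[Case], Sequence[Case], TrainConfig], TrainedModel]


def _default_trainer(train_cases, val_cases, cfg: TrainConfig) -> TrainedModel:
    model, _ = train(train_cases, val_cases, cfg)
    return model


def cross_validate(
    cases: Sequence[Case],
    cfg: TrainConfig,
    k: int = 10,
    seed: int = 0,
    trainer: Optional[Trainer] = None,
) -> CVReport:
    """Rotating k-fold cross-validation with pooled evaluation metrics.

    Segmentation DSC is summarized over label-bearing evaluation cases
    only; staging metrics pool every case's single evaluation-fold
    prediction.  A custom ``trainer`` (e.g. a stub) may replace the full
    training loop.
    """
    trainer = trainer or _default_trainer
    ss = np.random.SeedSequence(seed)
    split = make_fold_split(len(cases), k, np.random.default_rng(ss.spawn(1)[0]))
    rot_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(k)]

    per_rotation: list[dict] = []
    per_case: list[dict] = []
    pooled = ConfusionTable2x2(0, 0, 0, 0)
    dsc_pool: dict[str, list[float]] = {"tumor": [], "rectum": [], "mesorectum": []}

    for r in range(k):
        train_idx, val_idx, eval_idx = split.rotation(r)
        if not eval_idx:
            raise ValidationError(f"rotation {r} has an empty evaluation fold")
        cfg_r = replace(cfg, seed=rot_seeds[r])
        model = trainer([cases[i] for i in train_idx], [cases[i] for i in val_idx], cfg_r)
        records, table = evaluate_cases(model, [cases[i] for i in eval_idx], cfg_r)
        for rec in records:
            rec["rotation"] = r
            for name in dsc_pool:
                if f"dsc_{name}" in rec:
                    dsc_pool[name].append(rec[f"dsc_{name}"])
        per_case.extend(records)
        pooled = pooled + table
        per_rotation.append(
            {
                "rotation": r,
                "n_eval": len(eval_idx),
                "confusion": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
                "sensitivity": sensitivity(table),
                "specificity": specificity(table),
                "accuracy": accuracy(table),
            }
        )

    summaries = {
        name: summarize_dsc(vals) for name, vals in dsc_pool.items() if len(vals) > 0
    }
    return CVReport(
        k=k,
        seed=seed,
        folds=split.folds,
        per_rotation=per_rotation,
        pooled_confusion=pooled,
        pooled_sensitivity=sensitivity(pooled),
        pooled_specificity=specificity(pooled),
        pooled_accuracy=accuracy(pooled),
        dsc_summaries=summaries,
        per_case=per_case,
    )
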