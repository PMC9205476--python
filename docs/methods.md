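# Methods

This note records the model, the synthetic data, the numerical choices
and the open design decisions behind `rectalseg`, in the spirit of a
model-description appendix. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Segmentation model

The network is a 3D U-Net-style encoder–decoder. With `levels = L` and
`base_channels = B`, level `l` carries `B·2^l` channels.

* **Encoder.** Level 0 is one convolution block (convolution + batch
  normalization + ReLU). Each deeper level first downsamples with a
  stride-2 3×3×3 convolution block, then applies one convolution block.
  The stride-1 block kernel is configurable per level as 3×3×3 or 1×3×3;
  by default the full-resolution level uses 1×3×3 (cheap through-plane
  extent where the acquisition is thin) and all others 3×3×3. The exact
  placement of the two kernel types and the channel widths of the
  original design are not recoverable, so both are configuration, not
  constants.
* **Decoder.** Each step upsamples with a 4×4×4 stride-2 transposed
  convolution block, passes the matching encoder feature through a
  1×1×1 convolution block (the skip connection), concatenates, and
  fuses with one convolution block.
* **Head.** A 1×1×1 convolution to 3 channels and a per-channel
  sigmoid. Channel order is fixed: (tumor, rectum, mesorectum).
  Sigmoid rather than softmax is load-bearing: the tumor mask overlaps
  the rectum mask by construction, so the channels must be independent.

Input spatial dimensions must be divisible by `2^(L−1)`. Defaults are
`L=4, B=16`; the desk-scale experiments use `L=3, B=8`.

The whole network — convolutions, transposed convolutions, batch
normalization, the activations and Adam — is implemented directly in
NumPy with hand-written backward passes. Convolutions loop over kernel
offsets, contracting strided slices against `(C_out, C_in)` weight slabs
through BLAS; this keeps memory flat and is faster than an im2col GEMM
at the patch sizes used here. Correctness of every backward pass is
established by a finite-difference check of the full network plus loss
in the test suite (float64, step 1e−4). One known exact identity is
used as a test guard: a convolution bias feeding batch normalization has
zero gradient, since the batch mean removes it.

## Staging rule

Probability maps are binarized at a strict threshold (`p > 0.5`; a voxel
exactly at the threshold is background). The case is ≥T3 exactly when
`count(tumor ∧ ¬rectum) > 0`. The rectum mask includes its own contour
voxels, so "completely included in the rectum" and "no tumor voxel
outside the rectum mask" coincide; whether a tumor that touches the
outer rectal contour *from inside* should already count as T3 cannot be
settled from the rule's verbal description, so the default follows the
containment dichotomy and an optional `contour_strict` mode (boundary
extraction by face-connectivity erosion) implements the stricter
reading. An empty predicted tumor mask classifies ≤T2 with an explicit
`tumor_empty` quality flag instead of raising — this keeps
cross-validation total while surfacing failed segmentations.

## Loss

* Soft Dice loss per channel, smoothed with ε = 1 added to numerator and
  denominator: `1 − (2Σpg + ε)/(Σp + Σg + ε)`. ε defines the empty-mask
  case (both empty → 0) and bounds gradients; for nonempty masks the
  smoothed and plain values differ by at most `1/(Σp+Σg+1)`. Channels
  are averaged unweighted.
* Staging loss `−[(1−g)/2 + g·p_staging]` with `g ∈ {−1,+1}` and
  `p_staging = maxᵢ p_tumor,i (1 − p_rectum,i)`. The formula is linear in
  `p_staging` with slope exactly `−g`; its range is [−1, 0]. The printed
  source formula is typographically ambiguous and is labeled a
  cross-entropy; the adopted grouping is the unique reading consistent
  with the described behavior on T2 and T3 cases, and it is linear, not
  logarithmic. A log variant was considered and not adopted.
* The max is a hard max; the gradient flows through the (first) argmax
  voxel. A temperature-smoothed log-sum-exp variant exists behind a
  function (`staging_probability_smooth`) for experimentation and is
  unused by default.
* Combined objective `Loss_SEG + λ·Loss_STG` with λ = 0.02. The Dice
  term is evaluated only for label-bearing cases; the staging term for
  all. λ = 0 reproduces the dice-only baseline exactly.

## Preprocessing

Millimeter physical coordinates, 0-based voxel indices, voxel-center
convention. The chain is: trilinear resample to an isotropic target
(default 0.5 mm; masks nearest-neighbor), crop a fixed patch (default
256×256×128) centered on the user-supplied tumor center, z-score the
intensities (constant patches map to zeros; masks are never
normalized). Out-of-volume crop regions are padded with the volume's
minimum intensity (avoids bright borders on MR-like data) and 0 for
masks. Whether the original pipeline normalized at all, and with which
interpolation kernel it resampled, is unstated; z-scoring and trilinear
interpolation are the package's choices.

## Training protocol

Batches contain exactly 3 labeled + 2 staging-only cases drawn uniformly
with replacement from their pools each iteration (no epoch scheme is
pinned by the protocol; uniform re-draws keep the two pools at a fixed
ratio regardless of their sizes). If one pool is empty the batch falls
back to the other with a logged warning. Adam uses lr 0.003, β₁ 0.9,
β₂ 0.999, ε 1e−8. Every `validate_every` (default 100) iterations the
validation set is scored and the checkpoint with the best
(mean DSC + sensitivity + specificity) is retained; DSC is averaged over
the three structures of the labeled validation cases (whether the
original selection averaged or kept structures separate is unstated),
and an undefined term (a one-class validation fold) contributes zero.
Augmentation draws per sample: physical scale in [0.9, 1.1] (a pure
metadata rescale — exact, no interpolation), in-plane rotation in ±10°
about the through-plane axis, and slice-thickness conversion to a value
in [2, 4] mm before isotropic resampling. Magnitudes are not stated in
the source protocol; these are deliberately mild.

Cross-validation partitions cases into k = 10 seeded random folds;
rotation `r` evaluates on fold `r`, validates on fold `(r+1) mod k` and
trains on the rest — one concrete reading of "the remaining two folds
are validation and evaluation" — so each case is evaluated exactly once.
DSC summaries (median, IQR) pool label-bearing evaluation cases only;
staging metrics pool all cases. All randomness flows from one master
seed split into named substreams (folds, weight init, batches,
augmentation).

## Synthetic phantoms

The generator emulates an axial T2-weighted rectal acquisition:

* nested tubes along one axis — dark lumen, dark muscularis propria
  (wall), bright mesorectal fat annulus, intermediate background —
  optionally with a gentle sinusoidal centerline curvature;
* a tumor as an angular-sector thickening of the wall with a smooth
  quadratic cap in (angle, length) so its radial extent tapers to zero
  at the margins; `invasion_depth_mm ≤ 0` keeps it strictly inside the
  outer wall boundary (≤T2), positive values push the cap into the fat
  (≥T3). The case's stage is derived from the rendered voxel masks, so
  label and geometry cannot drift;
* anisotropic default grid (0.5×0.5 mm in-plane, 3.5 mm effective slice
  pitch: 3 mm slices + 0.5 mm gap) so isotropic resampling is genuinely
  exercised;
* Rician noise (magnitude of signal plus complex Gaussian), the standard
  statistics of magnitude MR images;
* a mucinous variant whose tumor mean sits close to the fat signal,
  emulating the near-isointense mucinous appearance that degrades
  segmentation.

Tissue intensity means are free parameters (no intensity statistics
exist to calibrate against); the defaults produce fat ≫ tumor > wall >
lumen contrast at roughly 20:1 peak SNR. What phantoms deliberately do
**not** model: MR sequence physics (k-space, TR/TE), organ motion and
deformation, lymph nodes, the mesorectal fascia, partial-volume mixing
at tissue borders (tissues are hard-assigned before noise), and realistic
texture. Passing the synthetic gates therefore demonstrates that the
pipeline's mechanics — geometry handling, the loss, selection, staging —
work end to end; it does not predict accuracy on patient images, whose
published counterparts cannot be reproduced here since the images are
not deposited.

## Desk-scale experiment sizes

Full-protocol sizes (0.5 mm / 256×256×128 patches, hundreds of cases) are
impractical for a NumPy network on one CPU, so the bundled experiments
shrink the geometry while keeping every mechanism: phantoms are
generated at 1 mm in-plane / 4 mm slices on 56×56×12 grids with
proportionally scaled anatomy (mesorectal radius 8–9.5 mm).

* **End-to-end gate:** 40 training / 10 validation / 20 evaluation
  phantoms, 24³ patches at 1 mm, `L=3, B=8`, 400 iterations with
  augmentation, validation every 100. Gates: held-out median DSC ≥ 0.7
  (tumor) and ≥ 0.85 (rectum, mesorectum), staging accuracy ≥ 0.8 —
  artifact acceptance gates on synthetic data, not claims about
  clinical performance.
* **Ablation:** λ = 0.02 vs λ = 0 across 5 seeds with shared cohorts,
  initialization and batch order; 28/8/16 phantoms, 20³ patches, 300
  iterations, validation every 50. The cohort uses shallow ≥T3 breaches
  (1–2 mm) — borderline cases are precisely where a stage-aware loss
  should matter, which is the term's original motivation. The gate is
  directional: mean staging accuracy with the combined loss must not be
  below the dice-only baseline.

## Numerical details and edge cases

* float32 throughout the network; losses in float64.
* Batch-norm: momentum 0.1, ε 1e−5; inference uses running statistics.
* He-normal weight initialization (fan-in), zero biases.
* DSC of two empty masks is 1.0 (perfect agreement on absence);
  sensitivity/specificity/accuracy return NaN sentinels on empty
  denominators rather than raising.
* Tumor diameter is the largest axis-aligned bounding-box extent in mm —
  deterministic and fast; a max Feret diameter can exceed it by up to
  √3, which is acceptable for the 20 mm small-tumor cutoff it serves.
* Non-finite training loss or gradients abort with a diagnostic rather
  than silently continuing.
* `binarize` uses a strict inequality, so a probability of exactly 0.5
  maps to background.

## Known limitations

* The NumPy network trains at desk scale only; the architecture is
  faithful but the published channel widths/depth are unknown and the
  defaults here are smaller.
* Phantom realism is geometric, not radiometric (see above); mucinous
  difficulty is emulated only through isointensity.
* The hard-max staging gradient updates one voxel per case per step;
  training signals from the staging term are therefore sparse, which is
  the faithful reading but makes λ ≫ 0.02 unstable.
* `tumor_diameter` underestimates oblique tumors relative to a Feret
  diameter.
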