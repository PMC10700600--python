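# Methods

## Overview

`hypovol` implements the full workflow of automated small-structure
brain volumetry: a slice-wise encoder–decoder segments both a small
low-contrast midline target and the intracranial compartment from
T1-like volumes; volumes are quantified from the predicted masks,
normalized to head size, quality-controlled with interquartile-range
fences, and compared between a case and a control group.  A synthetic
phantom generator supplies inputs with exact ground truth, so the
package's claims are checked by computation rather than by reference to
external data.

## The phantom generator

Each phantom is a bright ellipsoidal intracranial compartment
(intensity 0.75) on a dark background (0.10) containing a bilateral
target — two mirrored half-ellipsoids with fixed aspect ratio
(1 : 1.2 : 2, elongated along the slice axis) whose flat faces flank a
midline plane — at an additive contrast offset (+0.20) from the
surrounding tissue.  Default desk-scale geometry is a 64×64×24 grid at
0.75×0.75×1.0 mm (≈14 cm³ compartment, 300 mm³ target); a full-scale
block (512×512 px at 0.125 mm in-plane, 50 slices of 0.5 mm, ~0.8 cm³
target) is available via `PhantomSpec.full_scale()`.  The desk target
is deliberately large relative to the compartment compared with real
anatomy (≈2% rather than ≈0.05% of ICV) so that it still spans a
meaningful number of voxels on a grid small enough for CPU training.

Voxelization of the target samples each candidate voxel on a 3×3×3
sub-grid and keeps the `round(Σ occupancy)` highest-occupancy voxels;
the realized mask volume therefore tracks the analytic volume to within
one voxel (well inside the 5% discretization tolerance asserted by the
tests) at every grid scale.  The cut planes of the two halves are
snapped midway between voxel columns so no voxel is split lengthwise by
a flat face.

**Cohorts.**  Per subject, the head-size-normalized target volume is
drawn log-normally (guaranteed positive) around the group mean — the
case mean reduced by `effect_fraction` — with coefficient of variation
`between_subject_cv`; the ICV is drawn normally (redrawn if
non-positive).  The raw target volume scales proportionally with the
subject's drawn ICV (allometric exponent 1).  This coupling is a
modeling choice: observed normalized volumes in atrophy studies have a
smaller CV than raw volumes, implying a strong head-size/structure
correlation, and without it ICV normalization would only add noise
instead of removing head-size variance.  Per-scan contrast is varied by
a global affine intensity transform (gain ~U(0.9, 1.1), offset
~U(−0.05, 0.05)) plus additive Gaussian noise (σ = 0.02); the defaults
mirror the dispersion of published cohorts at our scale (normalized CV
8%, ICV CV ≈ 8.5%, effect 10%).  Generation is bit-deterministic per
seed, with per-subject seeds spawned from the cohort seed.

What the phantom does **not** emulate: cortical anatomy and
surrounding gray-matter structures of similar intensity, partial-volume
gradients, bias fields beyond an optional linear multiplicative ramp,
or motion/distortion artifacts.  Passing tests therefore demonstrate
the correctness and internal consistency of the pipeline — not
clinical-grade segmentation difficulty; real data are harder than these
phantoms, and absolute Dice values here are optimistic.

## Preprocessing

Rigid alignment rotates the volume about its center so the
anterior–posterior landmark axis becomes parallel to the slice normal
(residual angle < 0.1°); block resampling extracts a fixed
`block_plane_size² × block_slices` grid at requested spacings centered
on the target centroid (or a supplied landmark).  Intensities are
interpolated linearly, labels with nearest-neighbour — standard
practice that keeps masks binary and preserves mask volume within the
~5% interpolation tolerance checked by the tests.  The interpolation
kernel for upsampling was an open choice; linear was selected as the
least surprising default.

## Augmentation

Training sets are expanded `factor`-fold (default 6) with globally
contrast-shifted copies: the min–max-normalized image is mapped through
`clip(g·xᵞ + b, 0, 1)` with g ~U(0.5, 1.5), b ~U(−0.2, 0.2),
γ ~U(0.7, 1.4), then rescaled to the input range.  The transform family
and ranges are package choices; the requirement driving them is that
the transform be global and intensity-monotone (up to clipping) so
anatomical structure is preserved.  Masks are never modified.

## The segmenter

A 2-D U-topology network: `depth` encoder stages (default 2) that halve
resolution and double width from `base_channels` (default 8), a
bottleneck, a mirrored decoder with nearest-neighbour upsampling and
skip concatenation at each resolution, and a 1×1 softmax head with two
classes (background/foreground).  Inputs are z-scored per image inside
the forward pass (identical at training and inference), every
convolution is followed by group normalization (batch-size independent
and deterministic, unlike batch norm), and the head bias is initialized
to the log class frequencies of the training labels.  These three
choices address the rare-foreground optimization problem: without them
the net can settle into the all-background cross-entropy optimum on
unlucky data draws under short schedules, and converges several times
slower otherwise.  One model is trained per task (target
structure; ICV).  Four block styles emulate the flavor of common
classification backbones — stacked convolutions (vgg-like), residual
blocks with projection shortcuts (resnet-like), parallel 1×1/3×3
branches (inception-like), depthwise-separable units (efficient-like,
the smallest parameter count, as asserted by a test).  They are
reduced-width emulations, not layer-for-layer replicas, and train from
seeded random initialization (no pretrained weights — transfer learning
only shortens training and is unnecessary on phantoms).

The forward and backward passes (im2col convolutions, pooling argmax
routing, softmax/cross-entropy/soft-Jaccard gradients) and the Adam
optimizer are implemented in numpy and verified against
finite-difference directional derivatives in the tests; everything is
float32 and deterministic per seed.

**Loss.**  Categorical cross-entropy averaged per pixel plus
`1 − J_soft` with the soft Jaccard computed over the foreground class
pooled per batch (per-image versus per-batch pooling was an open
choice; per-batch is smoother for slices with little or no foreground).

**Protocol.**  Batch 4, Adam 10⁻³/0.9/0.999 (ε = 10⁻⁷), at most 25
epochs, early stopping after 10 epochs without validation-loss
improvement, argmin-epoch weights restored.  The pipeline defaults
scale this down (6 epochs with patience 4 for the target task, 2 for
the easier ICV task, 12 labeled volumes with 2 held out for
validation, augmentation factor 1) so a full study runs in about 1.5
minutes on one CPU; these are the problem sizes used by the end-to-end
tests and the acceptance script, and they reach held-out Dice ≈ 0.99
on desk phantoms.

**Degenerate-fit restart.**  Despite the measures above, particular
cohort draws can still end a short schedule in the all-background
optimum (zero validation IoU).  The pipeline's training stage then
restarts with deterministically re-derived initialization and shuffling
seeds, at most three attempts; in practice one restart suffices.

**Prediction** is per-slice argmax stacked into a volume mask, with
per-slice wall time recorded and an all-empty output flagged for QC.

## Metrics

Confusion counts are exact voxel counts per volume; IoU, precision,
recall and Dice follow, with zero-denominator cases reported as
undefined rather than 0, and metrics averaged across subjects (not
pooled over voxels).  HD95 extracts boundary voxels by 6-connected
erosion (array edges count as background), computes directed
boundary-to-boundary Euclidean distances via an exact distance
transform with anisotropic spacing, takes the linear-interpolation 95th
percentile of each directed set, and combines them with the maximum.
Combining by max versus pooling the two directed sets was an open
choice; max is the stricter and more common reading, and is recorded in
`metrics.HD95_COMBINATION`.  Note that with interpolated percentiles
HD95 equals the exact Hausdorff distance only for degenerate
(single-point) boundary sets; it is bounded above by it always.
Bland–Altman analysis reports d̄, ±1.96 SD limits, CI of the mean
`d̄ ± t·SD/√n`, and CI of each limit `LoA ± t·√(3SD²/n)`.

## Volumetry, normalization and QC

`V_norm = V_target / V_ICV × mean control ICV` — exactly
scale-invariant and the identity when the subject's ICV equals the
reference.  QC proceeds per group through a fixed cascade: (1) empty
target or ICV segmentation, (2) ICV outside its group Tukey fences,
(3) raw target volume outside fences, (4) normalized volume outside
fences; each subject carries the first-triggered reason.  Fences use
type-7 (linear-interpolation) quartiles, are computed once per stage
from the survivors of the previous stage, and are frozen — re-running
QC on the accepted subset flags nobody new.  The cascade order and the
per-group fencing are package decisions (the workflow literature
reports mixed rejection reasons without an explicit precedence); both
are recorded per subject in the outputs.  A group-stage with fewer than
4 survivors skips fencing (quartiles not estimable).  The normalization
reference defaults to the mean ICV of controls accepted through stage 3.

## Group statistics

Method agreement uses a Shapiro–Wilk gate (α = 0.05) on the paired
differences: paired t-test if normality is not rejected, otherwise
Wilcoxon signed-rank, with the branch recorded; zero-variance
differences produce a degenerate report instead of a fabricated
p-value.  Group differences use the two-sided pooled-variance (Student)
unpaired t-test — pooled rather than Welch was an open choice and is
recorded in the output.  Percent difference is
`(mean_control − mean_case)/mean_control × 100`, emitted both to one
decimal and as the nearest integer; the control-mean denominator is the
convention under which the reference arithmetic (10/14/4/3%) is
reproduced.  Group summaries use the sample SD (n−1), undefined (NaN)
for single-subject groups.

## Orchestration and reproducibility

`run_pipeline` derives one seed per stage (cohorts, augmentation,
weight init, shuffling) from the single global seed via
`SeedSequence.spawn`, writes every artifact (manifest, per-subject
metrics, cohort results with QC reasons, fences and acceptance rates,
stats report with the agreement analysis, training curves, model
weights + JSON sidecars) and a provenance file with the config hash and
all derived seeds.  Because the whole stack is numpy, a rerun with the
same config is bit-identical — including training.

## Known limitations

- At the default schedule the desk-scale segmenter is nearly unbiased
  (volume-agreement bias of a few mm³ on a 300 mm³ target); recovery of
  a simulated group effect is then limited by cohort sampling noise
  (SE of the percent-difference estimate ≈ 1.5 points at n = 60/60),
  not by segmentation error.  Under-trained models instead over-segment
  and pull both group means toward the training-set average, shrinking
  the contrast.
- Desk-scale geometry keeps the target's voxel count modest; Dice
  values are not comparable across grid scales.
- The phantom's high target/background separability means segmentation
  failure modes of clinical data (contrast collapse, motion) appear
  only when explicitly simulated (e.g. `target_contrast → 0`).
- HD95 assumes voxelized boundaries; no sub-voxel surface model.
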