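# Methods

This note records the models, procedures and numerical conventions used
by `ossiseg`, the choices made where the design was genuinely open, and
what the synthetic phantoms can and cannot establish about clinical data.

## The segmentation model

### VB-Net

Each cascade stage is a V-Net-style 3D encoder–decoder whose stages are
built from bottleneck residual units ("VB-Net"): one input block, four
down blocks, four up blocks, one output block and a softmax head.

* **Input block**: k×k×k convolution (k = 3) to the base width, instance
  normalization, ReLU.
* **Down block**: one strided convolution (kernel k, stride s = 2, so
  each of the four encoder levels halves every spatial dimension; 16×
  total) followed by the block's bottleneck units. Input patches must
  therefore be divisible by 16 per axis; violations raise a shape error.
* **Bottleneck unit**: 1×1×1 convolution reducing channels by the
  reduction factor (default 4), a k×k×k spatial convolution, a 1×1×1
  expansion back to the block width, residual addition, ReLU. Instance
  norm + ReLU follow the first two convolutions.
* **Up block**: a 2×2×2 stride-2 transposed convolution doubling
  resolution, a skip connection from the matching encoder level, then
  bottleneck units. Skips are concatenated and merged by a 1×1×1
  convolution by default; element-wise addition is available
  (`skip_mode="add"`) when decoder widths mirror the encoder.
* **Output block**: 1×1×1 convolution to the class count; probabilities
  via softmax.

Channel widths and bottleneck counts per block are configuration. The
`full` preset uses 16/32/64/128 encoder channels with 1–2 bottlenecks
per block; the `desk` preset uses 8/16/32/64 with one bottleneck per
block so the whole pipeline trains on one CPU. Normalization and
activation choices (instance norm, ReLU) are the standard ones for
small-batch 3D segmentation. Weight initialization is seeded He-normal,
so identical configurations and seeds build identical networks.

### Why a numpy engine

The network, its backpropagation and the Adam optimizer are implemented
directly on numpy (`ossiseg.nn`): convolutions run as im2col + BLAS
matrix products, the data gradient of a strided convolution is evaluated
as a stride-1 convolution of the zero-dilated output gradient with the
flipped transposed kernel, and the 2× transposed convolution is an exact
per-voxel linear map. This keeps the package dependency-light and fully
deterministic on CPU. Every layer's input and parameter gradients are
pinned against central finite differences in the test suite, and an
overfit-one-sample test (Dice loss < 0.1 within 200 steps) guards
end-to-end gradient flow.

## The coarse-to-fine cascade

**Training.** The coarse stage is binary: its ground truth is the union
of the three structure labels dilated by 10 mm in each direction with an
axis-aligned box structuring element (`ceil(10 / spacing)` voxels per
axis — a Chebyshev ball in voxel space), and patch centers are drawn
uniformly over the whole image at 1 mm spacing. The fine stage is
4-class at fine spacing; patch centers are drawn uniformly from voxels
within a Chebyshev distance of 20 voxels of the merged foreground.
"Within 20 pixels" is read per-axis to match the per-axis phrasing of
the 1 cm expansion, and is realized as a box maximum filter.

**Inference.** The whole image is resampled to 1 mm isotropic,
normalized, padded per axis to the next multiple of 16 (temporal-bone
volumes at 1 mm are small enough for a single whole-volume pass) and
pushed through the coarse network. The foreground probability is
thresholded at 0.5 and the largest 26-connected component's bounding box
is kept — the minimal post-processing consistent with "roughly locate";
an all-background prediction raises a localization error rather than
returning silently. The box is expanded by 20 mm per face (clamped to
the grid), cropped from the *original* image, resampled to fine spacing,
and covered with overlapping tiles (50 % overlap; per-class
probabilities averaged over overlaps, then argmax). The fine labels are
pasted back to the original grid by nearest-neighbor lookup; an oracle
round-trip test (ground-truth-emitting predictors injected in place of
the networks) bounds the loss of this whole geometric chain at
per-structure DSC ≥ 0.95 on default phantoms, in practice ≥ 0.98.

**Loss.** Total = soft Dice + cross entropy with unit weights. The
coarse Dice is single-class (foreground only); the fine Dice averages
the three ossicle classes with equal weights. Background is excluded
from the fine average — the single-class coarse loss sets the
foreground-centric reading — but can be included via a switch. Smoothing
ε = 10⁻⁵ in the Dice denominator defines the empty-prediction case, and
empty-vs-empty is defined as zero loss. A "×100 %" in the conventional
Dice formula is a percentage notation artifact and is treated as ×1,
keeping losses in [0, 1].

**Optimization.** Adam with initial learning rate 10⁻², betas
(0.9, 0.999), L2 decay 10⁻⁴; step schedule multiplying the rate by 0.1
at 50 % and 75 % of the epoch budget (the schedule's breakpoints are a
choice; only "step schedule, initial 10⁻²" is fixed). An epoch is a
fixed number of sampled patches (100 at full scale, 64 in the desk
preset — an epoch definition is inherently a choice when patches are
sampled on the fly). Early stopping monitors validation loss — epochs
are selected by minimum validation loss, so "loss stopped decreasing" is
read as validation loss — with patience 20 epochs; the retained
checkpoint is the validation minimum. Validation patches are drawn once
at fixed seeded locations so per-epoch losses are comparable.

**Cohort handling.** `split_dataset` draws a seeded random 8:1:1
train/validation/test split; 158 cases give exactly 126/16/16.
Five-fold validation redraws an independent seeded 8:1:1 split per fold
(repeated random subsampling, not disjoint folds) and averages the five
test-set accuracies — fidelity to the described procedure over the
classic convention.

## Intensity normalization

Default: `clip((x − 1000) / 1500, −1, 1)` — a fixed bone window with
level 1000 HU and width 3000 HU, mapping 1000 HU to exactly 0 and
anything above 4000 HU to exactly 1. An alternative convention maps
[−2000, 4000] HU linearly to [−1, 1] (slope 1/3000); both are expressible
through the `(level, width)` parameters, and the clipping-window form is
the default because it is the machine-readable configuration of the two.

## Geometry conventions

* Voxel indices are 0-based and node-centered: physical position =
  origin + index × spacing (mm). One convention everywhere.
* Resampling: output shape = `round(shape × spacing / target)` clamped
  ≥ 1 per axis; origin preserved; trilinear interpolation for images,
  nearest neighbor for labels (nearest never invents labels). Nearest
  ties (an output center exactly between two input centers) resolve to
  the higher index; tests assert distance-optimality rather than a
  specific tie winner.
* Patch cropping pads out-of-volume regions with −1 (the normalized air
  value) for images and 0 for labels; out-of-bounds centers are legal,
  and a placement record allows exact paste-back.

## Evaluation metrics

* DSC on voxel sets; empty-vs-empty is defined as 1.
* Boundaries: foreground voxels with ≥ 1 background 6-neighbor
  (out-of-grid counts as background); surface points are their physical
  centers in mm.
* ASD: directed mean nearest-neighbor distance as printed; the reported
  scalar is the symmetric average of both directions, with directed
  values available.
* HD/HD95: maximum, resp. 95th percentile (linear interpolation), of
  the pooled two-directional nearest-neighbor distance set, so
  HD95 ≤ HD always; the one-directional variant is available. Whether
  published HD95 values pool both directions is generally ambiguous;
  pooling is the default here.
* Distances are physical (mm). Sub-voxel ASD values at fine spacing are
  only meaningful in mm.
* Method comparison: two-sided paired t-tests per structure per metric;
  identically-performing methods (zero-variance differences) return a
  degenerate flag rather than a number.

All four metrics are verified against exhaustive O(|X|·|Y|) pairwise
brute-force references to 10⁻⁹ on random mask pairs.

## The phantom generator

Each phantom is a petrous-bone-intensity block (+1800 HU) with one
ellipsoidal air pocket (−900 HU, the tympanic cavity; exterior air
−1000 HU at one face) containing three disjoint ossicle-like solids at
+2200 HU, built from constructive geometry:

* malleus (label 1): sphere head fused with a cylindrical handle,
  default length 8 mm;
* incus (label 2): ellipsoid body with a long and a short process,
  default 6.5 mm;
* stapes (label 3): flat elliptical footplate joined to a small head by
  two oblique crura, default 3 mm — always the smallest structure, as in
  the real anatomy.

Per-case variability: ±10 % size jitter, ±0.1 rad rotations, sub-mm
translations (all scaled by the `jitter` parameter). Labels mark voxels
whose centers lie inside each solid; the image applies a 0.35-voxel
Gaussian blur as a partial-volume stand-in, adds Gaussian noise
(sd 40 HU) and rounds to integer HU. Thin parts are floored at a radius
of 0.62 × max spacing so every structure remains one 26-connected
component at any resolvable spacing. All HU sit inside the normalization
window; the ossicle–cavity contrast exceeds 1000 HU by construction, so
the desk-scale task is learnable. Output is a pure function of
(spec, case seed); per-case seeds derive from the dataset seed via
`SeedSequence([seed, case_index])`.

**What the phantoms do not emulate** — CT physics (beam hardening,
scatter, detector noise correlations), true ossicle morphology and
articulations, surrounding anatomy (cochlea, canals, facial nerve),
pathology/malformation, scanner protocol variation. Passing desk-scale
tests therefore demonstrates that the pipeline's mechanics (geometry,
optimization, cascade hand-off, metrics) are correct and that the
cascade can learn a high-contrast small-structure task end to end; it
does not certify clinical accuracy, which requires real labeled HRCT.

## Desk-scale study conditions

The default end-to-end configuration, chosen once from CPU throughput
estimates: 24 phantoms (64³ at 0.3 mm), 20 train / 4 held out via the
seeded 8:1:1 split, reduced cascade (8/16/32/64 channels), 32³ patches,
coarse spacing 1 mm, fine spacing 0.3 mm (the phantom's native grid),
30 epochs per stage at 64 patches/epoch, batch 4. The whole pipeline
runs in about 6 minutes on one CPU. At this budget the cascade reliably
solves combined-foreground delineation (held-out foreground DSC ≈ 0.98);
per-structure class assignment improves with longer fine-stage training
and is not part of the desk-scale headline.

## Known limitations

* The engine is CPU-only and unbatched beyond small batch sizes; the
  `paper` preset documents full-scale settings but is impractical
  without hardware acceleration.
* Volumes are axis-aligned (no oblique orientation matrices); DICOM
  ingestion is out of scope (NIfTI and MetaImage only).
* No data augmentation, no test-time augmentation, no uncertainty
  estimation; bilateral instance separation is not attempted (cases are
  single-sided).
* Exact channel widths/bottleneck counts of the reference architecture
  are not published in machine-readable form; the defaults here are
  reasonable stand-ins exposed as configuration.
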