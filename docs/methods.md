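# Methods

`dixonfat` quantifies abdominal subcutaneous (SAT) and visceral (VAT)
adipose tissue on single axial fat-only Dixon MRI slices. This note
documents the models, the parameters that matter, the synthetic phantom
the test suite runs against, and the numerical choices made where the
design was genuinely open.

## Problem and pipeline

On a fat-only Dixon image adipose tissue is bright and other soft tissue
dark. Single-slice protocols quantify fat at standardized disc levels
(L2–L3 and L4–L5) by (i) delimiting the abdominal wall with two nested
regions — an outer region out to the skin and an inner region enclosing
the abdominal cavity — and (ii) classifying bright fat pixels. SAT is fat
between the two boundaries (the wall ring); VAT is fat inside the inner
region. The package implements two routes to these labels:

1. **Reference (semi-automated) route** (`dixonfat.reference`): threshold
   fat at a fraction (default 50%) of the maximum signal over the trunk,
   exclude spurious fat islands (spinal canal / neural foramina) via an
   exclusion ROI and optional minimum component area, then split fat into
   SAT/VAT by the nested regions. Scripted edit operations stand in for
   the interactive corrections a reader would make.
2. **CNN route** (`dixonfat.nn`, `dixonfat.fusion`): two depth-4 U-Nets —
   one segmenting background / wall ring / inner region, one classifying
   background / SAT / VAT — whose outputs are fused into the final
   four-class label map.

## Dixon decomposition

The two-point Dixon identity is implemented exactly: with in-phase
IP = W + F and out-of-phase OP = W − F, `dixon_decompose` returns
W = (IP + OP)/2 and F = (IP − OP)/2. The map is linear and its inverse
(`dixon_recompose`) holds to machine precision; tests treat this as an
algebraic identity, not an approximation.

## Networks and loss

Both models are standard U-Nets: `depth` (default 4) encoder levels of two
3×3 conv + ReLU blocks with channel doubling and 2×2 max-pooling, a
bottleneck, and a mirrored decoder (2× nearest-neighbor upsampling + 3×3
conv, skip concatenation, two 3×3 convs), finished by a 1×1 head and a
softmax. With a 384-pixel input and depth 4 the bottleneck is 24×24.
There is no normalization layer and no augmentation; weights use He
initialization from a seeded generator.

The stack is implemented on a compact numpy reverse-mode autodiff
(`dixonfat.nn.autodiff`) with channels-last activations; each 3×3
convolution runs as nine BLAS matrix multiplications (one per kernel
tap), which keeps single-core CPU training practical at the problem sizes
used here.

**Generalized Wasserstein Dice loss.** Inter-class confusions are weighted
by a symmetric ground-distance matrix M with zero diagonal. For pixel i
with true class t_i and predicted probabilities p_i the transport error is
W_i = Σ_l M[t_i, l] p_{i,l}. Errors aggregate Dice-style against the
background class b:

    TP   = Σ_{i : t_i ≠ b} (M[t_i, b] − W_i)
    loss = 1 − (2·TP + ε) / (2·TP + Σ_i W_i + ε)

A one-hot-correct prediction gives exactly 0; with M = 1 off the diagonal
the expression reduces to a generalized-Dice form. The smoothing ε
(default 1e-5) only guards the 0/0 case of an image with no foreground.
Per-image losses are averaged over the batch. Default matrices: all-ones
off-diagonal for the region task; for the fat task M(SAT, VAT) = 0.5 —
confusing the two fat depots is half as wrong as confusing fat with
background. Both matrices are configuration, not fixed constants.

**Class encodings.** Each network predicts 3 classes (region task:
background / wall ring / inner region; fat task: background / SAT / VAT).
This keeps the two models independently evaluable; fusion reconciles them
into the four-class output (outer region, inner region, SAT, VAT).

**Training recipe.** Adam, initial learning rate 1e-4, batch size 8, 100
epochs, reduce-on-plateau scheduler (patience 10 epochs, factor 0.1)
monitoring validation loss, best-validation-epoch weights retained, no
early stopping. Inputs are min-max normalized to [0, 1] and zero-padded
symmetrically to the network input size (see below). One master seed fans
out to initialization, the subject-level train/validation split, and batch
shuffling; on a fixed BLAS build runs are bit-reproducible. The scheduler
type/factor and the absence of augmentation are this package's choices
where the recipe leaves them open. For the scaled-down phantom experiments
in the test suite (128×128 inputs, base 8 channels, 160 training slices) a
larger initial learning rate of 5e-4 and ~24 epochs are used: the Dice
-family loss is plateau-prone at 1e-4 on such small, high-contrast
problems, while rates ≥1e-3 can collapse the prediction to background.

## Fusion

Raw region predictions are repaired before use: largest connected
component per region, interior hole filling, and clipping the inner
region to the outer region eroded by one pixel so nesting is strict.
Clean inputs pass through unchanged. Fat pixels are then gated
geometrically: any predicted fat pixel inside the inner region becomes
VAT, in the wall ring SAT, outside the trunk background. The geometric
gate is the default because it is the only combination rule that
guarantees the anatomical invariants (VAT confined to the cavity, SAT to
the ring); `region_override=False` instead trusts the fat model's own
SAT/VAT call and uses the regions only as masks. A threshold fallback
mode replaces the fat network with the reference 50%-of-max labeling
inside the CNN regions, mirroring how a reader would override a
suboptimal CNN result; both modes emit the same output schema.

## Input geometry

Acquisitions reconstructed at 288×288 are brought to the 384×384 network
input by symmetric zero-padding (intensity-preserving, exactly invertible
by center-cropping); bilinear resampling is available as an alternative
mode, with nearest-neighbor semantics for masks. Padding is the default
because it introduces no interpolation error into label maps. Conventions
throughout: 0-based (row, col) indexing, masks as boolean pixel sets,
contour vertices in continuous pixel coordinates with pixel centers at
integers. Contours are traced at iso-level 0.5 with sub-pixel precision
(one contour per component, largest first; holes negatively oriented) and
rasterized by an even-odd point-in-polygon test at pixel centers, so
lattice-aligned simply-connected regions round-trip exactly.

## Reference-labeling choices

The threshold comparison is inclusive (≥), making the boundary case
testable. The reference maximum is taken over the outer-region support
rather than the whole image so out-of-body artifacts cannot inflate it;
a robust variant (e.g. the 99.5th percentile) is available by
configuration. Island removal defaults to ROI-based exclusion only
(`min_area = 0`); size filtering is opt-in, since in practice islands are
excluded by a reader-drawn ROI rather than a size rule.

## Evaluation

Per class: Dice similarity coefficient 2|A∩B|/(|A|+|B|), with the
both-empty convention DSC = 1 (slices with no VAT occur); areas in pixels
and cm² (pixels × spacing² / 100); Pearson correlation of areas;
Bland–Altman bias and limits of agreement (mean ± 1.96 SD of paired
differences, sample SD with n−1); two-sided paired Student's t-test, with
the degenerate all-equal case reported as (t = 0, p = 1). Cross-validation
is fivefold and **subject-disjoint**: all scans of a participant share a
fold, preventing longitudinal leakage; the aggregate is the unweighted
mean of per-fold means. Correlation/agreement statistics are computed on
areas in cm² (pixel counts are also emitted). Trunk-relative ratios
(SAT/outer, VAT/inner, (SAT+VAT)/outer) summarize fat burden
independently of body size.

## The phantom generator

`dixonfat.phantom` emulates axial fat-only abdominal slices so that every
stage is testable without the (confidential) study cohort. A phantom is a
smoothly-perturbed ellipse (radius modulated by angular harmonics of
order 2–4) with a bright SAT ring of angularly varying thickness, bright
VAT disks scattered in the cavity, darker non-fat tissue, an optional
bright posterior fat island standing in for spinal-canal fat that the
reference pipeline must exclude, plus additive Gaussian noise and a
smooth multiplicative bias field (bounded by 1 ± amplitude). Defaults:
384 px, 1.1 mm spacing, fat 600 / tissue 150 intensity units (the >2×
contrast guarantees the 50% rule is exact on clean phantoms), noise SD 10,
bias amplitude 0.15. L4–L5 phantoms carry a thicker wall and more VAT
blobs than L2–L3, mirroring per-level reporting without claiming
anatomical fidelity. Cohorts draw per-subject base geometry from
configurable ranges and drift it across visits as a small random walk
(~2% per visit), which is what makes subject-level fold splitting
meaningful. The per-subject visit-count distribution is a configuration
knob (`visit_counts_for_total` reproduces a target scan total, e.g. 474
scans over 136 subjects at two levels).

What the phantom does **not** emulate: Rician noise statistics (Gaussian
is used for simplicity), in-phase/out-of-phase acquisition physics, coil
sensitivity profiles, motion or chemical-shift artifacts, organ texture,
or real anatomical shape variation. Passing phantom tests therefore
demonstrates correctness of the algorithms and the learning machinery,
not clinical-grade performance on patient images.

## Numerical choices and degenerate inputs

* Argmax ties in prediction break toward the lower class index, so a
  uniform probability field yields background.
* Noise is clipped at zero after degradation (magnitude images are
  non-negative); with tissue intensities well above the noise floor the
  clip never triggers.
* `normalize_intensity` rejects constant images; `threshold_fat` rejects
  an empty support; `enforce_nesting` raises naming the region whose
  prediction is empty.
* Phantom specs are validated for frame fit, wall positivity, and
  inner-region feasibility before rendering; cohort draws clamp the wall
  thickness into the feasible band for the drawn ellipse.
* Float32 is used inside the network stack; statistics are computed in
  float64.

## Problem sizes in the test suite

The end-to-end learning checks train both U-Nets at 128×128 with base 8
channels on 160 phantom slices from 40 subjects and evaluate on 40 slices
from 10 unseen subjects; held-out recovery is scored after the package's
own nesting repair, i.e. on the output of the actual inference path. The
reproduction script (`scripts/acceptance.py`) reruns the same experiment
from a user-supplied seed.
These sizes were chosen to keep a full run on one CPU core practical
while leaving the architecture (depth 4, two models, Wasserstein Dice
loss, subject-disjoint splitting) identical to the full-scale setting.

## Known limitations

* Single 2D slices only; no 3D volumes, no DICOM-RT, no GUI.
* The numpy training stack targets small CPU experiments; it has no GPU
  path and no convolution fusion, so full-scale (384×384, 100-epoch)
  training is slow, though functional.
* Cohort-level results reported for the original clinical study are not
  reproducible here: that cohort is private, and the phantom makes no
  claim of matching its difficulty. The package reproduces the *method*
  and verifies it on data whose ground truth is exact by construction.
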