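# Methods

## Problem and approach

Segmenting cardiac structures in 3D MR volumes is dominated by two
practical constraints: the structures of interest occupy a small
fraction of the field of view, and full-resolution 3D networks are
memory-hungry. The package implements a coarse-to-fine answer. A small
3D encoder–decoder (the *localizer*) sees a downsampled copy of the
volume and is trained to predict the binarized union of the foreground
structures. From its final decoder feature maps a gradient-weighted
class activation map (GCAM) is computed:

    GCAM_c = ReLU( Σ_k x_k · ∂S_c/∂x_k )

where `x_k` is the k-th feature channel and `S_c` a scalar class score.
For a dense localizer there is no classification scalar, so `S_c` is
defined as the sum of the class-c pre-activation outputs over all voxels
— the standard dense-prediction extension. The map's intensity-weighted
centroid (over voxels ≥ 50% of the map maximum) places a fixed-size
axis-aligned region of interest in full-resolution index space; a
second, identical-architecture network (the *segmenter*) then segments
inside that crop at native resolution. The two trainings are disjoint:
no gradient crosses the crop (multi-stage strategy).

The end-to-end strategy instead trains both networks jointly: the
localizer's single-channel sigmoid output is upsampled to input
resolution and fused with the input — element-wise multiplication by
default (an attention gate; with a unit attention map the model reduces
exactly to the segmenter alone), or concatenation as a second channel
(`e2e_fusion: concat`).

## Architecture

Both networks are 3D dilated-residual U-Nets: three encoder blocks,
a dilated bottleneck, three decoder blocks with skip connections, and a
1×1×1 head (sigmoid for one class, per-voxel softmax otherwise). Each
block is two 3×3×3 convolutions, each followed by batch normalization
and ReLU; the block input is concatenated with the second convolution's
output and projected back to the block width by a 1×1×1 convolution
(the "residual-as-concatenation" link). Channel widths double per level
(`base`, `2·base`, `4·base`; bottleneck `8·base`). Pooling is 2×2×2
max pooling, or 1×2×2 when `keep_z` is set so thick-slice short-axis
stacks are never pooled through-plane; the decoder mirrors this with
nearest-neighbour upsampling followed by convolutions (chosen over
transposed convolutions to avoid checkerboard artifacts).

The bottleneck is a chain of four 3×3×3 convolutions with dilation
rates 1, 2, 4, 8 whose four outputs are summed, giving a receptive
field of 2·(1+2+4+8)+1 = 31 voxels per axis at bottleneck resolution —
enough to cover the whole downsampled volume. The localizer at base
width 8 has 594,777 trainable parameters (asserted < 10^6 in the test
suite).

### Numerical core

No GPU framework is used: the package ships a compact numpy
reverse-mode automatic-differentiation engine (`locseg3d.nn`) with the
operations the architecture needs (broadcast arithmetic, matmul,
reductions, sigmoid/softmax, 3D convolution, max pooling, nearest
upsampling, batch norm, Adam). Convolutions are computed as one channel
matrix product per kernel tap over shifted views of the zero-padded
input; the input gradient is the correlation of the output gradient
with the spatially flipped, channel-transposed kernel, so forward and
backward share one code path. Every primitive is verified against
central finite differences (float64) in the test suite.

## Training

Optimization is Adam with decay rates 0.9/0.999. The full-scale
configuration (`RunConfig`) fixes the learning rate at 1e-4, which is
appropriate for runs of many thousands of steps. The estimator classes
default to 1e-3 because the package's desk-scale phantom runs take only
a few hundred steps, where 1e-4 demonstrably underfits; both are
plain parameters. Batch size defaults to 2, no augmentation. A fraction
(20%) of the provided training cases is held out as a validation split;
after each epoch the mean foreground dice on that split is recorded,
the best-scoring weights are checkpointed, and training stops early
when validation dice has not improved for `patience` epochs.

Losses: binary tasks use the sum of soft dice and voxel-mean binary
cross-entropy; multi-class tasks use the multi-class soft dice (mean of
per-class dice terms, background included). The `printed` dice variant
(no factor 2 in the numerator; a perfect hard prediction scores 0.5)
is retained as an option, `factor2` (minimum 0) is the default. Dice
smoothing constant is 1.0 in numerator and denominator; BCE predictions
are clipped at 1e-7.

The fixed ROI size, when not configured, is derived from the training
labels: the per-axis maximum foreground bounding-box extent plus a
10-voxel margin, rounded up to pooling divisibility and clipped to the
volume extent.

## Preprocessing

Optional slice-wise CLAHE (clip limit 0.03 on [0,1]-rescaled slices,
8×8 tiles), per-volume z-normalization (constant volumes map to zero),
optional resampling to a target spacing (linear for images, nearest for
labels; output shape is `round(shape·spacing/target)`), and symmetric
zero-pad / center-crop to a network-divisible shape with the odd
remainder on the high-index side. Every geometric step records its
inverse, so predictions are returned in the original input geometry.
The localizer input is produced by integer-factor block averaging
(nearest sampling for labels), in-plane only when `keep_z` is set.

## Evaluation

Dice similarity coefficient (both-empty pairs defined as 1), Hausdorff
distance and average symmetric surface distance, all boundary-to-
boundary with an exact Euclidean distance transform using the
anisotropic voxel spacing in mm. Boundary voxels are foreground voxels
with a background 6-neighbour, the volume border counting as
background. Hausdorff defaults to the symmetric max-of-both-directions
form; the directed form is available (`hd_mode`). Both distance metrics
are tested against O(N²) all-pairs oracles to 1e-9 mm. Volume agreement
uses Bland–Altman analysis on per-case volumes (foreground voxels ×
voxel volume, mm³): differences are taken as (manual − automated), bias
is their mean and the limits of agreement are bias ± 1.96·SD (n−1
denominator), so a method that over-segments shows a negative bias.

## Synthetic phantoms

Two regimes make every stage testable without data downloads:

* **blob** — near-isotropic volumes (default 16×64×64 at 0.625 mm
  isotropic) with one bright ellipsoid (semi-axes ~3.5×8×8 voxels,
  jittered) on a 0.2 background; emulates a high-resolution
  late-gadolinium-enhanced acquisition with a single atrium-like target.
* **shortaxis** — thick-slice stacks (default 12×64×64 at 8×1.4×1.4 mm)
  with, per slice, a bright disk (cavity), a darker ring strictly
  enclosing it (myocardium-like) and an adjacent bright crescent
  (right-ventricle-like), with per-slice centre drift and apical taper.
  This exercises the `keep_z` path and multi-class losses.

Both add Gaussian noise (sd 0.05), per-case contrast jitter, and a
smooth multiplicative bias field; generation is bit-reproducible under
the spec seed. `corrupt(v, level)` contracts intensity deviations around
the volume mean by `1−level` (halving the foreground/background gap at
level 0.5) and adds noise — used to emulate low-contrast, noisy scans.

What the phantoms do *not* emulate: MR physics (k-space artifacts,
motion, ghosting), anatomical shape variability beyond affine-ish
jitter, multi-modal intensity distributions, or inter-rater label
noise. Passing the phantom experiments therefore demonstrates that the
pipeline's machinery — localization, ROI propagation, losses, geometry
round-trips, training dynamics — is correct, not that clinical-grade
accuracy would be reached on real MR data.

## Reproduction experiments and problem sizes

`locseg3d.experiments` runs two end-to-end studies sized for a single
CPU (each a few minutes):

* blob study — 200 training / 40 held-out phantoms at 16×64×64,
  localizer on 4× in-plane downsampled input, ≤10 epochs with patience
  3. Reported: mean held-out full-resolution dice and the fraction of
  cases whose ROI contains ≥99% of ground-truth voxels.
* short-axis comparison — 48 training / 16 held-out corrupted
  (level 0.5) anisotropic phantoms; the multi-stage pipeline against a
  single-stage baseline of equal base width trained on the downsampled
  volumes and nearest-upsampled back. Reported: both mean dice values.

## Degenerate inputs and tie-breaks

Constant volumes z-normalize to zero; zero-dynamic-range slices pass
CLAHE unchanged. An identically zero density map raises a
`NoLocalization` error at the API level; the prediction path falls back
to an image-centred box and flags the case. ROI boxes are shifted
(clipped) inside the volume rather than padded, keeping segmenter input
statistics consistent; axes smaller than the crop are covered whole.
Max-pool argmax ties resolve to the first (lowest flat index) voxel.
Sigmoid outputs binarize at 0.5; softmax outputs by argmax.

## Known limitations

Training on real-scale volumes (e.g. 16×256×256) is possible but slow
on one CPU — the engine favours clarity and testability over
throughput. The data loader keeps entire case sets in memory. No
augmentation, no ensembling, no deep supervision. The GCAM and direct
sigmoid density sources usually give nearly identical boxes for
well-trained localizers; both are exposed (`roi_source`) because they
differ for poorly calibrated models.
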