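# Methods

`nucleiseg` implements a light-weight encoder-enhanced U-Net ("U-Net+")
for microscopy cell-nuclei segmentation, together with the two reference
networks it is compared against, the full data pipeline around them, and a
synthetic data generator that makes the whole loop testable on a laptop
CPU without any external dataset.

## The segmentation model

All three architectures are fully convolutional encoder–decoder networks
mapping a 256×256×1 grayscale patch to a 256×256×1 sigmoid probability
map.  The filter schedule is shared: level *n* of *N* uses 2^(n−1)·B
channels, with the base width B a multiple of 2 and the depth N = 5 by
default.

**U-Net+ (the package's core).**  The encoder is a triangular grid of
convolution blocks (conv 3×3, stride 1, zero padding, batch norm, ReLU).
Level 1 carries a chain of four blocks; each deeper level carries a
shorter chain (4, 4, 3, 1 blocks at N = 5).  Down-sampling blocks
(conv 3×3, stride 2, batch norm, ReLU) connect the levels column-wise:
every chain block at a level feeds a down block, and each conv block after
the first at the level below concatenates its same-level predecessor with
the corresponding down-sampled tensor.  One pathway chains two down
blocks in a row — the deepest down-sampled tensor of level 1 is
down-sampled again — and its arrival is concatenated both into the first
conv block of level 3 and into the decoder skip at that level, so raw
shallow detail reaches the decoder without passing through the deepest
layers.  A single down block produces the 16B-channel bottleneck.  The
decoder is U-Net-like: per level, 2× up-sampling — either a 3×3
stride-2 transposed convolution that halves the channel count ("T.C.")
or parameter-free row/column repetition that preserves it ("U.S.") —
followed by concatenation with the encoder skip(s) and two convolution
blocks.  The head is a single 1×1 convolution with sigmoid.

**Controls.**  `unet` is the classic reference U-Net (two plain 3×3 ReLU
convolutions per level, 2×2 max-pooling, repetition up-sampling followed
by a 2×2 convolution, two 3×3 convolutions after each skip concatenation,
and a 3×3 convolution to two channels before the 1×1 head).  `unet_pp` is
the nested-skip network (U-Net++): the same backbone plus the dense grid
of intermediate nodes, each a 2×2 transposed-conv up-sample concatenated
with all previous same-level nodes and followed by two 3×3 convolutions;
deep supervision and pruning are not implemented.  Neither control uses
batch normalization by default — with those conventions (and counting all
batch-norm parameters, including moving statistics, for U-Net+) the
builders reproduce the published per-model weight totals exactly at
B = 16 and B = 8, which is the structural acceptance surface that pins
down every wiring ambiguity:

| model | B=16 | B=8 |
|---|---|---|
| U-Net | 1,941,093 (1.941 M) | 485,813 (0.486 M) |
| U-Net++ | 2,261,601 (2.262 M) | 566,001 (0.566 M) |
| U-Net+ (T.C.) | 1,926,129 (1.926 M) | 483,833 (0.484 M) |
| U-Net+ (U.S.) | 1,730,049 (1.730 M) | 434,753 (0.435 M) |

The printed transposed-convolution stride of (1,1) cannot enlarge spatial
dimensions; the implementation uses stride (2,2) with kernel 3×3, which
both performs the required 2× up-sampling and reproduces the weight
totals.

## The NumPy network engine

The networks run on a compact reverse-mode autodiff engine written for
this package (`nucleiseg.nn`): NHWC tensors, convolution and transposed
convolution via im2col/col2im plus BLAS matrix multiplication, batch
normalization (momentum 0.9 on the moving statistics), 2×2 max-pooling,
nearest-neighbour up-sampling, concatenation, ReLU/sigmoid, and Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e−7).  Every layer's analytic gradient is
checked against central finite differences in the test suite.
Computation is float32; a full 256×256 forward+backward pass of the B = 8
U-Net+ takes roughly one second on one CPU core.

## Training objective and protocol

The loss is `λ_BCE · BCE(y, p) + mean_i −log D(y_i, p_i)` with the soft
Dice `D = (2·Σ y·p + s) / (Σ y + Σ p + s)` computed per sample over the
flattened maps.  Defaults: λ_BCE = 1.0, smoothing s = 1e−6 (keeps −log D
finite on empty intersections), probabilities clipped to
[1e−7, 1−1e−7] inside the cross-entropy.  The protocol defaults are
Adam at learning rate 5e−4 for 20 epochs with the checkpoint kept at the
lowest validation loss, and an optional fine-tuning phase of 5 epochs at
1e−4 under the same checkpoint rule; the checkpoint is seeded with the
entry state, so fine-tuning can never end worse than it started.  L2
regularization (λ, default 0 and 1e−4 as the published U-Net++ B = 16
setting) applies to convolution kernels only.  Batch size defaults to 16
but is a free parameter; the original setting ("fill the GPU") does not
transfer to CPU fixtures.

The **overfit capacity check** used by the acceptance suite trains the
B = 8 U-Net+ on eight synthetic 256×256 patches for 30 epochs at batch
size 1 — 240 optimizer steps in total.  At that schedule length the
full-dataset learning rate of 5e−4 is far from convergence, so the check
uses 5e−3; this is a property of the short schedule, not of the method.
It reaches training soft-Dice ≈ 0.98 and, after tiled inference and
post-processing on its own training images, per-cell average IOU ≈ 1.0,
in about five minutes on one CPU core.

## Data pipeline

*Preprocessing* (identical for training and inference): CLAHE (clip limit
0.01, 8×8 tile grid — the published pipeline names the algorithm but not
its parameters), Chambolle total-variation denoising (weight 0.1), then
affine rescaling to [0, 1] with constant images mapping to zero.

*Patching*: a structured grid with spacing 256 in both axes; images
smaller than 256 in a dimension are zero-padded; dimensions larger but
indivisible by 256 get one boundary re-crop flush with the image edge, so
every pixel is covered and patch count equals ⌈H/256⌉·⌈W/256⌉.  Random
patches are kept only when foreground/background pixel count ratio is
strictly greater than 0.4.  Patches are split 8:2 into train/validation
at the patch level (the published procedure; an image-level split avoids
leakage but is not the default).  Augmentation draws Gaussian/median/
average blur, contrast, saturation and hue jitter for the image, and
flips/right-angle rotations applied identically to image and mask;
hue/saturation on grayscale go through a temporary 3-channel copy and
return via Rec.601 luminance.  Augmentation runs on the full image before
preprocessing and patch extraction.

*Inference*: preprocess, decompose with the same grid rules, predict per
patch, fuse overlapping predictions by per-pixel maximum, crop padding,
threshold strictly above 0.5, remove 8-connected foreground components
with area < `min_object_area` and fill 4-connected holes with area <
`max_hole_area` (both default 300 px — "several hundred" is all the
original description fixes — and both config-exposed).  The acceptance
smoke uses 100 px for both because its synthetic nuclei have areas down
to ~120 px.  Touching nuclei are not split (no watershed); connected
components of the cleaned mask are the predicted instances.

## Evaluation

Predicted and ground-truth label maps are compared per cell with IOU.
For each threshold T ∈ {0.50, …, 0.95} a one-to-one assignment is made
greedily on descending IOU (ties: lower predicted label id); matched
ground-truth cells with IOU strictly above T are TP, the rest FN, and
unmatched predictions FP.  Precision is the mean over thresholds of
TP/(TP+FN+FP); an image with no ground-truth and no predicted cells
scores 1.0 (vacuous truth).  For T ≥ 0.5 the greedy assignment equals a
maximum bipartite matching — two disjoint ground-truth cells cannot both
overlap one prediction with IOU > 0.5 — so the matcher is oracle-exact
over the whole threshold range used.  Each ground-truth cell is also
assigned its matched IOU at the most inclusive threshold (0.50; the
original text leaves the choice within {T_k} open) or 0.0; the mean over
cells is the per-image average IOU, aggregated over images as mean ±
population standard deviation, alongside mean precision in percent.

## Synthetic data: what it does and does not emulate

Each sample draws 10–15 rotated ellipses (radius 8–12 px, axis ratio
0.6–1.0) with per-nucleus intensity in [0.55, 0.95] over a 0.15
background plus a low-order polynomial illumination field (amplitude 0.2)
and Gaussian noise (σ = 0.02); the nucleus layer is smoothed with a 1-px
Gaussian so boundaries are soft, the stated failure mode of interest.
Instances are disjoint and separated by at least one background pixel
unless touching is allowed.  Images are quantized to 8-bit levels so the
PNG round trip is lossless, and each sample is reproducible from
(seed, index) alone.

What this does **not** emulate: real stain/modality diversity, texture
inside nuclei, clustered/overlapping cells, annotation noise, or the
scale of the public nuclei datasets.  Passing the synthetic loop shows
the pipeline is wired correctly and that the network has the capacity to
segment simple nuclei; it says nothing about accuracy on real microscopy
data, which requires the external dataset and a full-scale training run.

## Numerical and degenerate-input choices

Rescaling a constant image returns zeros; CLAHE on a constant image
returns it unchanged; TV weight 0 is the identity.  Patch coordinates are
0-based (row, col) with half-open extents.  The train/val split size is
round(0.8·n).  Instance labels are always contiguous 1..K; loading
assigns them in lexicographic mask-file order; overlapping instance files
are an error, not merged.  Run-length encoding is column-major and
1-based with maximal runs.  The grayscale rule for mixed datasets is
pixel-wise channel equality.  Connectivity conventions are fixed at
8-connected foreground / 4-connected holes.

## Known limitations

Single-channel input only; no deep supervision, pruning, ensembling or
test-time augmentation (all deliberately out of scope); the CPU engine is
single-device and float32, so training beyond small fixtures is slow;
reproducing the published accuracy tables requires the external contest
dataset and GPU-scale training and is explicitly not attempted here.
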