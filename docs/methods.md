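# Methods

## Problem and model

The package segments colorectal polyps in colonoscopy frames: given an RGB
image, produce a per-pixel probability that the pixel belongs to a polyp.
The clinically hard cases are polyps with low contrast against the mucosa,
very small polyps, and very large ones, all under heavy background texture
(folds, specularities, vignetting).

The network is a symmetric five-level encoder–decoder kept deliberately
small (≤ 0.78 M learnable parameters) so that inference is feasible in real
time. Three context modules carry the modeling weight:

**Enhanced context-calibrated convolution (ECC).** Each level's feature
block splits its input `X ∈ R^{C×H×W}` by a learned 1×1 projection into two
`C/2` halves. The first half passes through a 1×1 conv–BN–ReLU
"identity-preserving" branch. The second half is filtered by a 3×3
depthwise-separable conv–BN–ReLU transform `F̂` and gated by a calibration
attention map

    X_att = σ( X₂ ⊕ Up( F̂₃ₓ₃( Down(X₂) ) ) ),

where `Down` is average pooling by the calibration rate, `Up` is bilinear
interpolation back to the input size, and σ is the sigmoid. Pooling before
filtering widens the effective receptive field cheaply, which is what lets
the gate suppress background tissue that locally resembles a polyp. The
gated product is refiltered by another `F̂`, concatenated with the identity
branch, and added residually to the block input, so the block is exactly
shape-preserving.

**Progressive context-aware fusion (PCF).** At the encoder bottleneck the
input is compressed 1×1 to `C/2`, then processed by a local 3×3 extractor
and a "surrounding" 3×3 extractor with dilation 5; their concatenation `x′`
restores `C` channels. A 1×1 convolution produces one logit per spatial
position; a softmax over all `T_p = H·W` positions gives attention weights
`β`, and the pooled vector `Σ_j β_j x′_j` passes through the bottleneck
transform `S₃ ReLU LN S₂` (layer-normalized two-layer channel bottleneck,
reduction 4). The output is `x + x′ + broadcast(context)`: the printed form
of the defining equation would drop `x′` from the output path entirely,
which would make the local/surrounding extractors unreachable by the
gradient except through the pooled scalar weights; we therefore keep `x′`
as the carrier and treat the skip as adding the uncompressed block input
(the only channel arithmetic consistent with an unprojected skip).

**Multi-scale pyramid aggregation (MPA).** The five decoder outputs are
bilinearly upsampled to the finest resolution, concatenated, and projected
1×1 to 32 fused channels. A squeeze-and-excitation gate — global average
pooling, a two-layer bottleneck of reduction 4, sigmoid — re-weights the
fused channels before the final 1×1 classifier. The concatenation order of
the five levels is normalized to (l₀…l₄); the following 1×1 projection
makes any fixed order equivalently expressive.

**Assembly.** Encoder: a dense 3×3 stem to 16 channels, then four 2×2
max-pool downsamplings with depthwise-separable channel transitions to
widths (16, 32, 64, 128, 160); one ECC block per level. Decoder: bilinear
2× upsampling, depthwise-separable width reduction, *additive* skip
connections, one ECC block per level. The ablation switch
(`baseline`/`ecc`/`pcf`/`mpa`/`full`) replaces ECC blocks by plain
depthwise-separable conv–BN–ReLU units and/or removes the PCF bottleneck
and MPA head. A single supervised output attaches to the final map; there
is no deep supervision.

## Loss

`L = 0.6·BCE + 0.4·Dice`, with Dice smoothed by ξ = 1e-8. BCE is the mean
over all pixels with probabilities clamped to [1e-7, 1−1e-7] before logs
(the defining sum is normalized to a mean so the loss scale is independent
of resolution). Dice is computed per image and then batch-averaged so that
frames with tiny polyps contribute equally. The printed form of the Dice
equation carries stray "+1" artifacts from typesetting; the standard
smoothed Dice is implemented.

## Numerical backend

All network math runs on a small reverse-mode autodiff engine inside the
package (`frcnet.nn`): a define-by-run tape over numpy arrays with
analytically derived backward passes for convolution (im2col for spatial
kernels, batched GEMM for 1×1), depthwise convolution, average/max pooling,
separable-matrix bilinear resampling (half-pixel centers), batch
normalization (biased batch statistics are written to the running buffers so
that frozen statistics reproduce training-mode normalization exactly),
layer normalization, softmax attention pooling, and the elementwise
algebra. Every backward pass is verified against central finite differences
in the test suite (relative tolerance 1e-4 on primitives, 1e-3 on whole
blocks). Default parameter dtype is float32; blocks accept float64 for
verification work. Max-pool gradients split ties evenly, keeping backward
passes deterministic. Forward passes are single-threaded and bitwise
reproducible.

Weight initialization is He-normal, drawn from one `numpy` generator
threaded through the build in a fixed order, so a model configuration plus
seed reproduces weights bitwise.

A note on calibration rates: the forward contract accepts any resolution
that is a multiple of 32. For an input side `32k`, the deepest two levels
see sides `4k` and `2k`, which are not generally divisible by 4, so ECC
blocks at levels 3–4 use calibration rate 2 while levels 0–2 use the
default rate 4.

## Metrics

Seven statistics per test set, each computed per image and averaged: mDice
and mIoU on predictions binarized at 0.5; MAE of the continuous map;
weighted F-measure (errors propagated from the nearest foreground pixel,
smoothed with a 7×7 σ=5 Gaussian, background errors discounted by
`2 − exp(ln(0.5)/5 · d)` with `d` the distance to the object); S-measure
(α = 0.5 blend of the object-aware mean/spread similarity and the
region-aware SSIM-like score over the four centroid quadrants); and the
enhanced-alignment E-measure swept over 256 equally spaced binarization
thresholds, reporting mean and max. The threshold grid uses bin midpoints
`(k+0.5)/256` strictly inside (0, 1), so the degenerate all-foreground
binarization at t = 0 is not part of the sweep and a perfect prediction
scores exactly 1; the `(HW−1)` normalizer of the alignment sum is capped at
1 for the same reason. Degenerate frames score 1 when both masks are empty
and 0 when a non-empty prediction meets an empty ground truth. Dice and
Jaccard obey `Dice = 2·IoU/(1+IoU)` per image, which the suite checks to
1e-12.

S-measure and weighted F-measure are exactly invariant to neither flips nor
rotations (centroid quadrant splits and distance-transform tie-breaks are
directional); the suite checks them to 0.02 under flips and the other five
metrics exactly.

## Synthetic scenes

The generator emulates what the segmentation task needs, not endoscopy
optics. A scene is: a reddish base color with per-channel jitter; a smooth
low-frequency luminance field (6×6 seeded grid, bilinearly upsampled,
amplitude 0.15); 1–3 fold-like Gaussian ridges of amplitude 0.05–0.12 as
distractors; polyps as star-convex blobs (boundary radius = base radius ×
(1 + 0.3 · two-lobe sinusoid, 3–7 lobes)) composited as intensity offsets
with a ~2 px feathered edge (offsets of overlapping polyps combine by
maximum so the configured contrast is what a measurement recovers); and
additive Gaussian noise (σ = 0.03). The stored mask is the exact blob
support. Defaults: 1–3 polyps, radius 0.06–0.28 of the image side, contrast
offset 0.08–0.5, so a default dataset mixes easy, low-contrast, small and
large polyps; named presets (`low_contrast`, `small`, `large`) isolate each
regime. The low-contrast preset is verified to defeat an Otsu luminance
threshold (mean Dice ≤ 0.5 over 20 scenes) while the mask stays exact —
the regime is genuinely hard for intensity evidence alone.

What the generator does *not* reproduce: specular highlights, instruments,
vignetting, motion blur, interlacing, true mucosal texture statistics, and
the correlation between polyp shape and appearance. Passing the desk-scale
learning checks therefore shows the implementation optimizes and segments
correctly end to end; it says nothing quantitative about performance on
real colonoscopy data, for which the published training protocol (512×512,
≥80 epochs, the public datasets) applies.

## Training protocol

Adam (β = 0.9/0.999, ε = 1e-8) at a fixed initial learning rate 1e-3 — no
schedule, as only the initial rate is specified — batch size 4,
augmentation by random horizontal/vertical flips, k·90° rotations, and
±20% brightness/contrast jitter (each applied with probability 0.5;
geometric transforms applied identically to the mask). A seeded 10% of the
training images is held out for validation; the checkpoint with the best
validation mDice is restored after the last epoch. The full-scale protocol
(512×512, ≥ 80 epochs) is the `TrainConfig` default; all tests and the
acceptance script run a desk-scale protocol — 200 scenes at 96×96 for 10
epochs — chosen as the smallest configuration at which the full model
comfortably exceeds 0.85 validation mDice and the ablation direction
(full > baseline) is observable.

## Design choices where the design was open

- ECC calibration rate: unspecified upstream; default 4 (2 at the deepest
  two levels, see above), average-pool down, bilinear up.
- The 1×1 "split" is one C→C convolution followed by a channel split; the
  first half feeds the identity branch.
- Batch norm: ε = 1e-5, momentum 0.1, per-batch statistics during training.
- PCF compression to C/2 so the two branch outputs concatenate back to C
  and the skip needs no projection; bottleneck ratio 4; LN is layer
  normalization over the pooled channel vector.
- MPA: fused width 32, SE ratio 4.
- Downsampling by max-pool rather than strided convolution (parameter
  budget; U-Net-like baseline).
- Encoder widths (16, 32, 64, 128, 160): chosen to meet the 0.78 M budget
  with margin (the full model is ≈ 0.37 M); the audit enforces the budget.
- Binarization at 0.5 for mDice/mIoU; the structure-aware metrics consume
  the continuous map.
- Validation split 10% by seeded shuffle; model selection by best
  validation mDice.
- Resizing: bilinear for images, nearest-neighbor for masks, masks
  re-binarized after any interpolation.

## Known limitations

- The numpy backend is CPU-only and single-threaded; the full 512×512 /
  80-epoch protocol is supported as configuration but is not practical on
  one core.
- The probability map is clamped to [1e-6, 1−1e-6] because float32 sigmoids
  saturate; gradients vanish there exactly as they do for a saturated
  sigmoid.
- E-measure equality with canonical GPU evaluation toolkits can differ in
  the last displayed digit because of the midpoint threshold grid and the
  cap at 1.
- Published benchmark figures on Kvasir-SEG/ClinicDB/ColonDB/ETIS/EndoScene
  require the real datasets and a full-scale training run; nothing in this
  repository asserts those numbers.
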