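# Methods

## Problem and model

`noduleseg` segments lung nodules in 64×64 single-channel CT-style
patches: each pixel is classified nodule / not-nodule.  The segmenter is
a compact encoder/decoder with three distinctive ingredients:

1. **Inverted residual blocks** in place of plain convolution pairs.
   Each block is a narrow–wide–narrow bottleneck: a 1×1 convolution
   expands the representation to `expansion ×` the block's filter count,
   a 3×3 *depthwise* convolution mixes spatially (per channel, 'same'
   padding), a squeeze-excitation (SE) gate rescales channels, and a
   linear 1×1 projection narrows back down.  The identity skip joins the
   narrow ends whenever stride is 1 and the channel counts agree.  All
   hidden activations are swish, x·σ(x) — smooth, non-monotone, bounded
   below by ≈ −0.2785, with no dead-neuron regime.
2. **A feature-pyramid-attention (FPA) bridge** between encoder and
   decoder at 16×16×64.  An attention branch max-pools the bridge input
   three times, convolving with 7×7, 5×5 and 3×3 filters (so the filters
   see large, medium and small context at 8×8, 4×4 and 2×2), applies one
   extra 3×3 convolution at the deepest level, then walks back up with
   learned 2×2 stride-2 transposed convolutions, fusing levels by
   addition.  The resulting pixel-wise map multiplies a 1×1-convolved
   main branch.
3. **Depthwise-separable cost structure.**  For an Hi×Wi×Di input, Dj
   output channels and f×f filters, a standard convolution costs
   Hi·Wi·Di·Dj·f² multiplications; the depthwise factorisation costs
   Hi·Wi·Di·(f²+Dj), a reduction of f²Dj/(f²+Dj) — asymptotically 9× for
   f = 3.  `blocks.conv_cost_standard` / `conv_cost_depthwise` /
   `cost_reduction_factor` implement this model exactly.

The full network (`networks.NetworkSpec` defaults) is:

```
input 64×64×1
encoder 1: 2 × IR(32)   → 64×64×32 ── skip ─────────────┐
maxpool                 → 32×32×32                      │
encoder 2: 2 × IR(64)   → 32×32×64 ── skip ───┐         │
maxpool                 → 16×16×64            │         │
FPA bridge              → 16×16×64            │         │
tconv 3×3 s2 (64→64)    → 32×32×64            │         │
concat                  → 32×32×128 ←─────────┘         │
decoder 1: 2 × IR(64)   → 32×32×64                      │
tconv 3×3 s2 (64→32)    → 64×64×32                      │
concat                  → 64×64×64 ←────────────────────┘
decoder 2: 2 × IR(32)   → 64×64×32
1×1 conv + sigmoid      → 64×64×1
```

Downsampling happens only by 2×2 max-pooling; the decoder's upsampling
layers are learned 3×3 stride-2 transposed convolutions.  The second one
halves the channel count (64→32), which is what makes the feature-map
table's `Upsampling layer 2 → 64×64×32` row and the subsequent 64-channel
concatenation dimensionally consistent — a parameter-free interpolation
could not change the channel count.

## Parameter-count calibration

The architecture's total of 891,713 trainable parameters is a hard
anchor, but several block-level details are under-determined: the
expansion factor; whether expansion and the SE bottleneck scale with the
block's input channels or its filter count; bias versus batch-norm
bookkeeping; the upsampling operators; an optional extra bottom
convolution in the pyramid; an optional global-pooling shortcut.
`scripts/calibrate_params.py` enumerates this discrete space
(~1.5k configurations) with closed-form per-layer arithmetic.  Exactly
one configuration matches 891,713:

* expansion 7, referenced to the block's **filter count** (output
  channels), so every block in a stage shares one expanded width;
* SE bottleneck `ceil(0.25 · filters)`, acting on the expanded features
  through two dense layers (swish then logistic gate);
* biases on every convolution, no normalisation layers;
* FPA with the extra deepest-level 3×3 convolution and 2×2 transposed-
  conv up-path; no global-pooling shortcut; the 1×1 convolution on the
  main branch;
* decoder upsampling by 3×3 stride-2 transposed convolutions.

That configuration is the shipped default, and the calibration script
re-verifies it against the real builder.  The uniqueness is a useful
sanity property: within the considered space, the printed count pins the
architecture down completely.

## Training recipe

Pixelwise-mean binary cross-entropy, minimised by Adam with β₁ = 0.99
(as published — deliberately higher than the conventional 0.9; a config
override exists), β₂ = 0.999, learning rate 10⁻³, weight decay 5·10⁻⁴.
The decay is implemented as *decoupled* weight decay on weight tensors
only (biases are never decayed); classic L2 is available via
`decoupled_weight_decay: false`.  Batch size 32, 200 epochs by default.
Weights are He-normal initialised from a single seed; runs are bit-
reproducible given (init seed, data seed, config).  A seeded 10 % carve-
out of the training split provides the per-epoch validation loss; the
best-validation weights are retained on the run log.

The numerical core is a purpose-built reverse-mode autodiff engine on
numpy (`noduleseg.nn`): NHWC layout, float32 training precision, fused
bias+activation per layer, im2col GEMM convolutions, and transposed
convolutions implemented as exact adjoints of stride-2 'same'
convolutions.  Gradients of every op are covered by float64 central-
difference checks in the test suite.

## The phantom generator

Real inputs would be LIDC-style 64×64 ROI patches around detected
nodules with radiologist masks.  The generator emulates their geometry:

* one bright quasi-circular nodule per patch; diameters are drawn
  uniformly from the clinically reported 3–30 mm range and mapped
  linearly to 4–56 px (the patch has no physical scale, so the mapping
  keeps all sizes representable);
* the ground-truth mask is exactly the closed Euclidean disk of pixel
  centres — pixel (r,c) is foreground iff its distance to the nodule
  centre is ≤ radius;
* nodule attachment classes: *well-circumscribed* (isolated),
  *juxta-pleural* (a bright wall band along the nearest patch edge,
  thick enough to touch the nodule), *juxta-vascular* (a bright
  vessel-like ridge through the nodule at a random angle).  Wall and
  vessel are drawn in the image only, never in the mask: the task is
  "nodule versus everything else", and discriminating the nodule from
  touching bright structures is precisely what makes those classes hard;
* background: a low base intensity plus smoothed Gaussian texture;
  nodule contrast uniform in [0.3, 0.6]; additive Gaussian pixel noise
  (σ = 0.03) and clipping to [0,1].

What the phantoms do **not** model: Hounsfield-unit calibration, partial-
volume effects, spiculated or part-solid nodule morphology, anatomical
context beyond one wall/vessel, scanner noise spectra, or inter-reader
mask variability.  Tests passing on phantoms therefore demonstrate that
the architecture, losses, metrics and pipeline are implemented correctly
and can learn this class of segmentation problem — not that the published
clinical accuracy would be reproduced on real CT data.

The augmentation/split pipeline mirrors the published bookkeeping:
horizontal flips double the dataset *before* the 80/20 split (2625 →
5250 → 4200/1050).  Because mirrored twins can land on opposite sides of
the split, the held-out set is not fully independent; this leakage is
inherited deliberately for count fidelity and noted here rather than
silently fixed.

## Preprocessing

`crop_and_resize` reproduces the ROI step: crop a half-open bounding box
from a larger image and resample to 64×64 bicubically (cubic-spline
interpolation, half-pixel centre convention).  Output pixel centres are
mapped into the *full* source image, so interpolation taps just outside
the box read real neighbouring pixels instead of invented padding; the
output is clipped to the input range, and a box already at the target
size is returned verbatim.

## Metrics

Dice, Jaccard/IoU, sensitivity and precision from pixel counts, with
explicit degenerate conventions (both masks empty → 1; empty prediction
against non-empty truth → 0 precision, and symmetrically for
sensitivity).  Batch evaluation reports both the macro average (mean of
per-sample metrics — the headline aggregate) and the pooled micro
variant, labelled, since published tables rarely say which was used.

## Problem sizes used by the test suite

Training at the published scale (4200 patches × 200 epochs) is a
multi-hour GPU-class workload and is out of scope.  The suite instead
exercises the full training path at two reduced scales chosen once:

* **overfit run** — 8 phantoms, 300 full-batch epochs, fixed seed; must
  reach training DSC ≥ 0.95 with final BCE below 10 % of the initial
  value (exercises every block's gradient path);
* **generalisation guard** — 24 phantoms → 48 after flips → 38 train /
  10 held out, 30 epochs at batch 8; held-out DSC must reach ≥ 0.85.

These sizes are regression guards for the implementation, not estimates
of clinical performance.

## Numerical and design notes

* Max-pooling ties route the gradient to a single element (argmax).
* `binarize` uses p ≥ threshold, so threshold 0 yields an all-ones mask.
* The logistic function is computed as ½(1+tanh(x/2)) — one
  transcendental pass, overflow-safe; BCE is evaluated in logit space.
* The FPA's 1×1 convolution sits on the main branch by default; the
  attention-branch placement, a global-pooling shortcut, and
  nearest-neighbour pyramid upsampling exist behind `PyramidConfig`
  flags, since published descriptions of pyramid attention differ on
  these points.  Neither placement is claimed to be the original
  authors' intent.
* Whether the published 200-epoch runs kept the final or the
  best-validation weights is unknown; the pipeline returns the final
  weights and retains the best-validation checkpoint on the run log.
* The classic U-Net baseline (depth 4, 64 base filters, 31.0 M
  parameters) is provided for comparison only; the published baseline's
  exact 8.6 M-parameter configuration is not described anywhere and is
  not reproduced.  At (depth 2, 32 filters) a classic U-Net is *smaller*
  than the attention network — the "always heavier" intuition holds from
  depth 3 up.

## Known limitations

* CPU-only; a training step on the full 891,713-parameter network over a
  batch of 8 patches takes a few seconds, so full-recipe runs (200
  epochs × 4200 patches) are impractical here.
* Stride is fixed at 1 in the inverted residual blocks (the architecture
  downsamples only via pooling); no 3-D variant; single foreground
  class; no test-time augmentation.
* The network is not architecturally flip-equivariant, and the package
  does not assert equivariance anywhere — flip consistency can be
  *reported* by evaluating flipped inputs, but it is not a contract.
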