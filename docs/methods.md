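# Methods

`octseg` quantifies laser-induced skin damage in OCT B-scan stacks in three
stages: speckle suppression by block-matching collaborative filtering,
semantic segmentation of the damaged region with an attention-augmented
UNet, and voxel-based volumetry of the predicted mask stack.  This note
records the models, the parameters that matter, and the design choices made
where the problem was genuinely open.

## Speckle model and denoising

OCT speckle is multiplicative interference noise.  The denoiser operates
directly on [0,1]-normalized intensities (a log-domain toggle is available
via `Bm3dConfig.log_domain` for strongly multiplicative regimes):

1. **Block matching.** For each reference position on a stride-4 grid
   (clamped so the last references touch the image border, which guarantees
   full pixel coverage without padding), all 8×8 blocks whose footprint lies
   in the 32×32 window centered on the reference are ranked by squared
   distance, ties broken by position for determinism.  The group keeps the
   closest blocks, trimmed to the largest power of two ≤ 16 because the
   group-axis transform is dyadic.
2. **Collaborative filtering.** Each block gets an orthonormal 2-D DCT; the
   group axis gets an orthonormal multilevel Haar transform.  Coefficients
   with magnitude below τ = `hard_threshold_coeff`·σ·√G are zeroed
   (G = group size).  The group-mean (approximation) coefficient is never
   thresholded, so constant images are exact fixed points.  σ is estimated,
   when not supplied, as MAD(HH₁)/0.6745 of the finest diagonal wavelet
   band.
3. **Aggregation.** All filtered member blocks are returned to their
   positions and averaged with weights inverse to the retained-coefficient
   count.  The full pass is iterated (twice by default), re-estimating σ
   each pass.

With the default τ semantics the filtering is deliberately conservative
(≈0.4σ at G=16); on the phantom this yields a small but strictly positive
PSNR gain and a consistent reduction of high-frequency spectral energy.
`threshold_mode="absolute"` interprets the coefficient as a fixed threshold
on normalized intensities (≈1.6σ at the phantom's noise level), which
filters far more aggressively; it is offered because the classical
collaborative-filtering literature uses thresholds near 2.7σ.  The default
stays with the σ-scaled reading.

## Attention operators

**SimAM** assigns each neuron the weight sigmoid(a) with

    a = ((x − μ)² + 2σ² + 2λ) / (4(σ² + λ)),

μ and σ² the per-channel spatial mean and *population* variance and
λ = 1e-4 a stability regularizer.  The population divisor keeps the formula
defined for 1-pixel-variance corner cases, with λ absorbing degeneracy.
The block has no learnable parameters.

**PSA** splits C channels into S = 4 groups, convolves group *i* with kernel
size (3,5,7,9)[i] at group count (1,4,8,16)[i] — clamped to
gcd(requested, branch width) so small decoder widths stay valid — squeezes
each branch by global average pooling through a two-layer bottleneck
(reduction 4, sigmoid output), softmax-normalizes the descriptors across
branches at every channel slot, and rescales the branch features.  The
closed-form parameter count (`psa_param_count`) mirrors exactly this
construction.

**Topologies.** tandem = PSA∘SimAM; parallel = elementwise mean (sum
optional) of the two branch outputs, chosen so the activation scale matches
either branch alone; nested = PSA with SimAM applied to each branch's
convolution output *before* descriptor pooling, suppressing noise during
multi-scale extraction.  No residual shortcut is added inside the combined
block.

## Segmentation network

A standard UNet: per encoder level a double 3×3 convolution (batch norm +
ReLU after each) and 2×2 max pooling; decoder levels use a 2×2 stride-2
transposed convolution, skip concatenation and a double convolution, after
which the configured attention block is applied (decoder-only insertion;
all decoder levels by default, restrictable via `attention_levels` when
channel divisibility fails).  A 1×1 convolution produces the class logits.
Weight initialization is He-normal from a seeded generator, so identical
seed + configuration gives bit-identical models, and full runs are
deterministic.

The full-scale defaults are base width 64, depth 5 (64→1024), input
512×512.  Parameter counts are reported by closed form and by enumeration;
they are not asserted against any external figure because they depend on
the exact widths chosen.

All tensor operations run on a small reverse-mode automatic-differentiation
engine over NumPy written for this package (`octseg.nn.autograd`):
convolutions are im2col + GEMM with the patch matrix shared between the
forward pass and the weight gradient.

## Training protocol

Weighted cross-entropy (mean over pixels of −w_y · log softmax), class
weights 1.0 background / 1.5 damage to counter class imbalance; Adam at
learning rate 1e-4 with weight decay 1e-4; gradient global norm clipped at
1.0; cosine learning-rate cycles with a 50-epoch period (the stated
"50-epoch period" of the regularization schedule is read as an LR schedule
with constant weight decay); 200 epochs at batch size 4; 8:1:1
train/val/test split by seeded permutation with floor rounding for val and
test.  The checkpoint with the best validation Dice is retained.  Metrics
are aggregated primarily over a pooled confusion matrix; per-image means
are also reported because the two conventions differ on small lesions.
Splitting is per-image by default; slice-level leakage between sets is a
known caveat for real stacks and a by-group split is the recommended remedy
when scan identifiers exist.

### Scaled benchmark

The reference experiment used throughout the tests trains each variant for
30 epochs at base width 16 / depth 3 / learning rate 1e-3 on the standard
40-pair 64×64 phantom benchmark (32/4/4 split).  The full-scale protocol is
impractical on one CPU; the scaled configuration keeps the loss, optimizer,
clipping and schedule and shrinks only capacity, resolution and epochs.
All four variants reach validation Dice well above 0.9 under it.

## Phantom generator

Each phantom is a layered cross-section: dark region above a bright surface
band (4 px at depth 12, intensity 0.85), then exponential depth decay
(rate 0.04/px) toward a 0.04 floor.  The lesion is an axis-aligned
ellipsoid whose intensity is multiplied by a contrast factor (jittered in
[1.5, 2.1] across the benchmark; radii jitter 6–12 px axially, 8–16 px
laterally; position jitter keeps the lesion inside tissue).  Noise is
multiplicative Gaussian speckle (σ = 0.30) plus additive Gaussian
(σ = 0.02), clipped to [0,1]; a Rayleigh speckle option exists.  Foreground
fractions fall in roughly 1–20% of pixels, matching the class-imbalance
regime the loss weighting targets.

What the phantom does *not* emulate: real OCT point-spread correlation of
speckle (noise here is pixel-independent), shadowing under lesions,
curvature and layering of real skin, motion artifacts, annotation noise in
manual labels.  Passing the phantom benchmark therefore demonstrates that
the pipeline's mechanics (denoising, learning, metrics, volumetry) are
correct and learnable, not that real-tissue accuracy figures transfer.

## Volumetry

Damage volume is V = V_P · Σ_k F(s_k) with F the foreground-pixel count per
slice and V_P = dx·dy·dz.  Default spacings: width→10 μm (lateral),
height→22 μm (axial, the system's longitudinal resolution), slice→50 μm,
giving V_P = 11,000 μm³.  Masks predicted at 512×512 are mapped back to
native scan geometry (inverse crop + nearest-neighbour resize, driven by
metadata recorded during preprocessing) before counting, because the
spacings are defined on native pixels.  No connected-component filtering is
applied.  The axis-to-spacing assignment is configurable; the published
spacing of the lateral axis is not fully self-consistent with the stated
scan width, so the geometry is exposed as configuration rather than
resolved.

The end-to-end check segments a denoised 16-slice phantom with a trained
model and compares V against the analytic ellipsoid volume
(4/3)π·r_z·r_y·r_x·V_P; a mid-sized lesion (radii 6, 10, 13 px) is used so
the comparison measures volume recovery rather than single-pixel boundary
discretization.

## Numerical choices and edge cases

- Dice of two empty regions is 1.0 (perfect agreement on absence); classes
  absent from the truth are skipped in mPA/mIoU with renormalized divisors.
- PSNR of identical images reports +inf as a sentinel.
- Block-match ordering and the train-loop shuffling both derive from seeded
  generators; identical input and configuration give bit-identical outputs
  everywhere, including BM3D.
- Max-pool gradients split ties evenly; ties are measure-zero for real
  inputs.
- Geometry preprocessing centers the 460×460 content in the 512×512 frame
  (symmetric 26-pixel borders) and stores scale/offset metadata for exact
  inversion; images are resized bilinearly, masks nearest-neighbour.

## Known limitations

- CPU-only; full-scale (512×512, width-64) training is functional but slow.
  The architecture and losses are standard, so behaviour transfers, but
  wall-clock figures do not.
- The comparison transformer baselines, learned denoisers and surface
  rendering of the damage contour are out of scope.
- The denoise-then-train benefit under the default conservative threshold
  is small; on easy phantoms the raw-noisy runs nearly match the denoised
  runs.
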