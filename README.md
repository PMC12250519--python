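# octseg

Quantitative analysis of laser-induced skin damage in OCT B-scan stacks:
speckle denoising by block-matching collaborative filtering, semantic
segmentation of damaged tissue with attention-augmented UNets, and
voxel-based damage volumetry across dose / recovery-time groups.

Swept-source OCT produces stacks of grayscale cross-sections (B-scans) of
skin.  Assessing how a laser lesion grows and heals requires segmenting the
damaged region in every slice and integrating its volume.  `octseg`
implements that pipeline for researchers working with small annotated OCT
datasets, plus a seeded synthetic phantom generator so every stage is
testable without any data download.

## The models

**Denoising.**  Speckle is suppressed by grouping similar 8×8 blocks inside
a 32×32 search window, hard-thresholding the group in a separable 3-D
transform domain (orthonormal 2-D DCT per block, orthonormal Haar along the
group axis) at τ = c·σ·√G with c = 0.1, and aggregating overlapping
estimates weighted by inverse retained-coefficient count, iterated twice.

**Segmentation.**  A UNet whose decoder stages carry a combined attention
block built from two operators:

- SimAM — parameter-free energy attention, per-pixel weight
  `sigmoid(((x−μ)² + 2σ² + 2λ) / (4(σ² + λ)))` from the channel's spatial
  statistics;
- PSA — pyramid squeeze attention: channels split into S = 4 multi-scale
  convolution branches (kernels 3/5/7/9) whose squeeze descriptors are
  softmax-normalized across branches.

Three topologies are available: **tandem** (PSA∘SimAM), **parallel**
(mean of the two branch outputs) and **nested** (SimAM inside PSA's
branches), alongside the plain UNet baseline.  Training uses weighted
cross-entropy (damage 1.5 : background 1.0), Adam (lr 1e-4, weight decay
1e-4, 50-epoch cosine cycles), gradient clipping at norm 1.0, batch size 4,
8:1:1 split.  Everything is NumPy; a small built-in reverse-mode autodiff
engine (`octseg.nn`) powers the networks, so runs are deterministic and
CPU-only.

**Metrics.**  Dice 2|X∩Y|/(|X|+|Y|) (fraction), plus accuracy, mean pixel
accuracy (mPA) and mean IoU (percent), all from a pooled confusion matrix.

**Volumetry.**  V = V_P · Σ_k F(s_k), with F(s_k) the damage-pixel count of
slice k and V_P = dx·dy·dz = 10·22·50 μm³ = 11,000 μm³ by default.

## Worked example

```python
import numpy as np
from octseg import BM3DDenoiser, UNetSegmenter, VoxelGeometry, damage_volume
from octseg.phantom import benchmark_set, generate
from octseg.benchmark import volume_recovery_spec

# 40 synthetic B-scans with ground-truth lesion masks
pairs = benchmark_set(40, seed=7)
X = np.stack([p.images.slices[0].pixels for p in pairs])
y = np.stack([p.truth.slices[0].labels for p in pairs])

X = BM3DDenoiser().transform(X)                      # speckle suppression

est = UNetSegmenter(variant="parallel", base_width=16, depth=3,
                    lr=1e-3, epochs=30, seed=7)
est.fit(X[:32], y[:32], validation_data=(X[32:36], y[32:36]))
print(f"best validation Dice: {est.best_val_dice_:.4f}")

# volumetry on a 16-slice phantom stack
pair = generate(volume_recovery_spec(seed=7))
masks = est.predict(BM3DDenoiser().transform(pair.images.as_array()))
vol = damage_volume(list(masks), VoxelGeometry())
print(f"damage volume: {vol.volume_um3:.3e} um^3 "
      f"(analytic {pair.analytic_lesion_volume(VoxelGeometry()):.3e})")
```

Output from this exact script:

```
best validation Dice: 0.9546
damage volume: 3.688e+07 um^3 (analytic 3.594e+07)
```

The validation Dice is the overlap between predicted and true lesion masks
on held-out phantoms (1.0 = perfect); the damage volume is the voxel count
of the predicted 3-D lesion times 11,000 μm³ per voxel, here within ~3% of
the analytic ellipsoid volume.

The same flow is scriptable from the shell:

```bash
octseg simulate --out data -n 12 --seed 0
octseg pipeline --out run --seed 0          # denoise→train→segment→volume
octseg pipeline --dump-defaults             # every configurable setting
```

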