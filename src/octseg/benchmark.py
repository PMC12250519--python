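"""The standard scaled-down phantom benchmark protocol.

This is the package's reference experiment: 40 seeded 64x64 single-slice
phantoms (8:1:1 split), BM3D denoising, and the four segmenter variants
(plain UNet, tandem, parallel, nested) trained for 30 epochs at base width
16 / depth 3 with Adam at 1e-3.  The full-scale defaults (base width 64,
depth 5, 200 epochs at 1e-4) are impractical on a single CPU; the scaled
protocol keeps the same architecture family, loss, optimizer, clipping and
schedule, shrunk until one variant trains in about a minute.

Also provides the end-to-end volume-recovery experiment: a 16-slice phantom
with a representative ellipsoidal lesion is denoised, segmented with a
trained model, and its voxel volume compared with the analytic ellipsoid
volume.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .denoise import BM3DDenoiser
from .phantom import (PhantomSpec, benchmark_set, generate,
                      standard_benchmark_spec, STANDARD_BENCHMARK_SIZE)
from .train import UNetSegmenter, split_dataset
from .volumetry import VoxelGeometry, damage_volume

__all__ = ["SCALED_TRAIN_KWARGS", "benchmark_data", "train_benchmark_variant",
           "volume_recovery_spec", "volume_recovery"]

#: scaled-down training configuration of the standard benchmark
SCALED_TRAIN_KWARGS = dict(base_width=16, depth=3, lr=1e-3, epochs=30,
                           batch_size=4)


def benchmark_data(seed: int, denoise: bool = True):
    """Generate the 40-pair benchmark and split it 8:1:1.

    Returns ((Xtr, ytr), (Xva, yva), (Xte, yte)); X arrays are denoised
    unless ``denoise=False`` (the raw-noisy arm of the paired comparison).
    """
    pairs = benchmark_set(STANDARD_BENCHMARK_SIZE, standard_benchmark_spec(),
                          seed=seed)
    X = np.stack([p.images.slices[0].pixels for p in pairs])
    y = np.stack([p.truth.slices[0].labels for p in pairs])
    if denoise:
        X = BM3DDenoiser().transform(X)
    tr, va, te = split_dataset(list(range(len(pairs))), (8, 1, 1), seed=seed)
    return (X[tr], y[tr]), (X[va], y[va]), (X[te], y[te])


def train_benchmark_variant(variant: str, data, seed: int) -> UNetSegmenter:
    (xtr, ytr), (xva, yva), _ = data
    est = UNetSegmenter(variant=variant, seed=seed, **SCALED_TRAIN_KWARGS)
    est.fit(xtr, ytr, validation_data=(xva, yva))
    return est


def volume_recovery_spec(seed: int) -> PhantomSpec:
    """16-slice phantom with a mid-sized ellipsoidal lesion (radii 6,10,13)."""
    return replace(standard_benchmark_spec(), slices=16,
                   lesion_center=(8, 36, 34), lesion_radii=(6, 10, 13),
                   seed=seed)


def volume_recovery(est: UNetSegmenter, seed: int,
                    geom: VoxelGeometry | None = None) -> dict:
    """Denoise -> segment -> accumulate voxel volume on a seeded phantom.

    Returns predicted and analytic volumes (um^3) and the relative error.
    """
    geom = geom or VoxelGeometry()
    pair = generate(volume_recovery_spec(seed))
    denoised = BM3DDenoiser().transform(pair.images.as_array())
    masks = est.predict(denoised)
    result = damage_volume(list(masks), geom)
    analytic = pair.analytic_lesion_volume(geom)
    return {
        "predicted_um3": result.volume_um3,
        "analytic_um3": analytic,
        "relative_error": abs(result.volume_um3 - analytic) / analytic,
        "predicted_voxels": result.total_voxels,
        "true_voxels": int(pair.truth.as_array().sum()),
    }
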