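"""Seeded synthetic OCT-like B-scan phantoms with ground-truth lesion masks.

A phantom volume emulates a layered skin cross-section: a dark air gap above
a bright surface band, then tissue whose backscatter decays exponentially
with depth.  A lesion is an axis-aligned ellipsoid (slice, row, col radii)
whose intensity is multiplied by a contrast factor.  Noise follows the
coherent-imaging model: multiplicative speckle plus additive Gaussian,

    I_noisy = I * (1 + eta_speckle) + eta_gauss,   eta ~ N(0, sigma)

clipped to [0,1].  A Rayleigh speckle option is available for heavier tails.
Identical seeds give bit-identical phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import BScanImage, ImageStack, MaskStack, SegmentationMask
from .volumetry import VoxelGeometry

__all__ = ["PhantomSpec", "PhantomPair", "generate", "benchmark_set",
           "standard_benchmark_spec", "STANDARD_BENCHMARK_SIZE"]

#: size of the standard phantom benchmark used by the training harness
STANDARD_BENCHMARK_SIZE = 40


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 64
    width: int = 64
    slices: int = 1
    surface_depth: int = 12          # first bright row
    surface_band: int = 4            # thickness of the bright entry band
    layer_decay: float = 0.04        # attenuation per pixel of depth
    surface_intensity: float = 0.85
    background_intensity: float = 0.04
    lesion_center: tuple = (0, 36, 32)   # (slice, row, col)
    lesion_radii: tuple = (0, 10, 12)    # (r_z, r_y, r_x) pixels
    lesion_contrast: float = 1.9     # multiplicative intensity factor
    speckle_sigma: float = 0.30
    gaussian_sigma: float = 0.02
    speckle_model: str = "gaussian"  # or "rayleigh"
    seed: int = 0

    def __post_init__(self):
        cz, cy, cx = self.lesion_center
        rz, ry, rx = self.lesion_radii
        if min(rz, ry, rx) < 0 or min(self.speckle_sigma,
                                      self.gaussian_sigma) < 0:
            raise ValueError("radii and noise scales must be >= 0")
        if not (rz <= cz <= self.slices - 1 - rz
                and ry <= cy <= self.height - 1 - ry
                and rx <= cx <= self.width - 1 - rx):
            raise ValueError("lesion ellipsoid does not fit inside the volume")


@dataclass
class PhantomPair:
    images: ImageStack           # noisy stack (network input)
    truth: MaskStack             # ground-truth lesion masks
    clean: ImageStack            # noise-free stack (denoising reference)
    spec: PhantomSpec

    @property
    def analytic_lesion_voxels(self) -> float:
        """Continuous ellipsoid volume in voxel units, (4/3)*pi*rz*ry*rx
        (degenerate axes fall back to the discrete foreground count)."""
        rz, ry, rx = self.spec.lesion_radii
        if min(rz, ry, rx) == 0:
            return float(self.truth.as_array().sum())
        return 4.0 / 3.0 * np.pi * rz * ry * rx

    def analytic_lesion_volume(self, geom: VoxelGeometry) -> float:
        """Analytic lesion volume in um^3 for the given voxel spacings."""
        return self.analytic_lesion_voxels * geom.voxel_volume


def _clean_profile(spec: PhantomSpec) -> np.ndarray:
    rows = np.arange(spec.height)
    profile = np.full(spec.height, spec.background_intensity)
    s0, s1 = spec.surface_depth, spec.surface_depth + spec.surface_band
    profile[s0:s1] = spec.surface_intensity
    deeper = rows >= s1
    profile[deeper] = (spec.background_intensity
                       + (spec.surface_intensity - spec.background_intensity)
                       * 0.65 * np.exp(-spec.layer_decay * (rows[deeper] - s1)))
    return profile


def _lesion_mask(spec: PhantomSpec) -> np.ndarray:
    cz, cy, cx = spec.lesion_center
    rz, ry, rx = spec.lesion_radii
    z = np.arange(spec.slices)[:, None, None]
    y = np.arange(spec.height)[None, :, None]
    x = np.arange(spec.width)[None, None, :]
    q = ((z - cz) / max(rz, 0.5)) ** 2 + ((y - cy) / max(ry, 0.5)) ** 2 \
        + ((x - cx) / max(rx, 0.5)) ** 2
    return (q <= 1.0).astype(np.int64)


def generate(spec: PhantomSpec) -> PhantomPair:
    """Build one phantom stack plus its ground truth, fully seeded."""
    rng = np.random.default_rng(spec.seed)
    profile = _clean_profile(spec)
    clean = np.broadcast_to(profile[None, :, None],
                            (spec.slices, spec.height, spec.width)).copy()
    mask3 = _lesion_mask(spec)
    clean = np.where(mask3 == 1, np.clip(clean * spec.lesion_contrast, 0, 1),
                     clean).astype(np.float32)
    if spec.speckle_model == "rayleigh":
        ray = rng.rayleigh(scale=1.0, size=clean.shape)
        speckle = spec.speckle_sigma * (ray - np.sqrt(np.pi / 2))
    else:
        speckle = spec.speckle_sigma * rng.standard_normal(clean.shape)
    noisy = clean * (1.0 + speckle) \
        + spec.gaussian_sigma * rng.standard_normal(clean.shape)
    noisy = np.clip(noisy, 0.0, 1.0).astype(np.float32)
    images = ImageStack([BScanImage(noisy[k], {"slice_index": k})
                         for k in range(spec.slices)])
    cleans = ImageStack([BScanImage(clean[k], {"slice_index": k})
                         for k in range(spec.slices)])
    truth = MaskStack([SegmentationMask(mask3[k], {"slice_index": k})
                       for k in range(spec.slices)])
    return PhantomPair(images=images, truth=truth, clean=cleans, spec=spec)


def benchmark_set(n: int, base: PhantomSpec | None = None,
                  seed: int = 0) -> list[PhantomPair]:
    """n phantoms with jittered lesion position/size/contrast.

    Jitter ranges (uniform): lesion row in [0.45, 0.72]*H, col in
    [0.3, 0.7]*W, row radius in [6, 12] px (scaled by H/64), col radius in
    [8, 16] px (scaled by W/64), contrast in [1.5, 2.1].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    pairs = []
    hscale = base.height / 64.0
    wscale = base.width / 64.0
    for i in range(n):
        ry = int(round(rng.uniform(6, 12) * hscale))
        rx = int(round(rng.uniform(8, 16) * wscale))
        cy = int(round(rng.uniform(0.45, 0.72) * base.height))
        cx = int(round(rng.uniform(0.30, 0.70) * base.width))
        cy = int(np.clip(cy, ry, base.height - 1 - ry))
        cx = int(np.clip(cx, rx, base.width - 1 - rx))
        contrast = float(rng.uniform(1.5, 2.1))
        spec = replace(
            base,
            lesion_center=(base.slices // 2, cy, cx),
            lesion_radii=(base.lesion_radii[0], ry, rx),
            lesion_contrast=contrast,
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        pairs.append(generate(spec))
    return pairs


def standard_benchmark_spec() -> PhantomSpec:
    """Base spec of the standard 40-pair, 64x64 single-slice benchmark."""
    return PhantomSpec()
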