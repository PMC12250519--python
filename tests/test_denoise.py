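"""Block matching, collaborative filtering, and denoising diagnostics."""

import numpy as np
import pytest

from octseg.denoise import (Bm3dConfig, BM3DDenoiser, PSNR_INF, band_energy,
                            bm3d_denoise, collaborative_filter, log_spectrum,
                            match_blocks, psnr)
from octseg.phantom import PhantomSpec, generate


class TestConfig:
    def test_defaults_are_the_stated_protocol(self):
        cfg = Bm3dConfig()
        assert (cfg.block_size, cfg.search_window,
                cfg.hard_threshold_coeff, cfg.iterations) == (8, 32, 0.1, 2)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            Bm3dConfig(block_size=64, search_window=32)
        with pytest.raises(ValueError):
            Bm3dConfig(iterations=0)
        with pytest.raises(ValueError):
            Bm3dConfig(hard_threshold_coeff=-0.1)


class TestMatchBlocks:
    def test_constant_image_full_group(self):
        img = np.full((40, 40), 0.5, np.float32)
        grp = match_blocks(img, (16, 16), Bm3dConfig())
        assert grp.group_count == 16
        assert grp.members[0] == (16, 16)

    def test_planted_duplicate_ranks_first_after_reference(self, rng):
        img = np.zeros((32, 32), np.float32)
        patch = rng.random((8, 8)).astype(np.float32)
        img[0:8, 0:8] = patch
        img[8:16, 8:16] = patch        # exact duplicate, non-overlapping
        grp = match_blocks(img, (0, 0), Bm3dConfig(max_group_size=4))
        assert grp.members[0] == (0, 0)
        assert grp.members[1] == (8, 8)
        # exhaustive-distance oracle: no other block matches exactly
        d = [float(((img[r:r + 8, c:c + 8] - patch) ** 2).sum())
             for r, c in grp.members]
        assert d[0] == d[1] == 0.0
        assert all(x > 0 for x in d[2:])

    def test_tiny_window_keeps_only_reference(self, rng):
        img = rng.random((24, 24)).astype(np.float32)
        grp = match_blocks(img, (8, 8), Bm3dConfig(search_window=8))
        assert grp.group_count == 1
        assert grp.members == [(8, 8)]

    def test_out_of_bounds_reference_rejected(self):
        with pytest.raises(ValueError):
            match_blocks(np.zeros((16, 16), np.float32), (12, 0))

    def test_distances_nondecreasing(self, rng):
        img = rng.random((48, 48)).astype(np.float32)
        grp = match_blocks(img, (20, 20), Bm3dConfig())
        ref = img[20:28, 20:28]
        d = [float(((img[r:r + 8, c:c + 8] - ref) ** 2).sum())
             for r, c in grp.members]
        assert all(d[i] <= d[i + 1] + 1e-9 for i in range(len(d) - 1))


class TestCollaborativeFilter:
    def test_constant_blocks_unchanged(self):
        img = np.full((40, 40), 0.6, np.float32)
        grp = match_blocks(img, (8, 8), Bm3dConfig())
        out = collaborative_filter(grp, Bm3dConfig(), sigma=0.05)
        assert np.allclose(out.blocks, grp.blocks, atol=1e-6)

    def test_zero_blocks_zero_retained(self):
        img = np.zeros((40, 40), np.float32)
        grp = match_blocks(img, (8, 8), Bm3dConfig())
        out = collaborative_filter(grp, Bm3dConfig(), sigma=0.1)
        assert np.allclose(out.blocks, 0.0)
        # only the always-kept DC slot survives, and it is zero-valued
        assert out.retained_coefficients == 1

    def test_single_block_zero_threshold_round_trip(self, rng):
        cfg = Bm3dConfig(search_window=8, hard_threshold_coeff=0.0)
        img = rng.random((16, 16)).astype(np.float32)
        grp = match_blocks(img, (4, 4), cfg)
        assert grp.group_count == 1
        out = collaborative_filter(grp, cfg, sigma=1.0)
        assert np.abs(out.blocks.astype(np.float64)
                      - grp.blocks).max() < 1e-6


class TestDenoise:
    def test_constant_image_fixed_point(self):
        img = np.full((32, 32), 0.5, np.float32)
        out = bm3d_denoise(img)
        assert np.abs(out.pixels - img).max() < 1e-6

    def test_deterministic(self):
        pair = generate(PhantomSpec(seed=5))
        a = bm3d_denoise(pair.images.slices[0])
        b = bm3d_denoise(pair.images.slices[0])
        assert np.array_equal(a.pixels, b.pixels)

    def test_psnr_gain_and_high_frequency_suppression(self):
        gains = []
        for seed in range(3):
            pair = generate(PhantomSpec(seed=50 + seed))
            noisy, clean = pair.images.slices[0], pair.clean.slices[0]
            den = bm3d_denoise(noisy)
            gains.append(psnr(den, clean) - psnr(noisy, clean))
            assert band_energy(den) <= band_energy(noisy)
        assert np.mean(gains) > 0

    def test_output_range_and_shape(self):
        pair = generate(PhantomSpec(seed=6))
        out = bm3d_denoise(pair.images.slices[0])
        assert out.pixels.shape == (64, 64)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0

    def test_transformer_api(self):
        pair = generate(PhantomSpec(seed=8, slices=2))
        den = BM3DDenoiser()
        arr = pair.images.as_array()
        out = den.fit_transform(arr)
        assert out.shape == arr.shape
        params = den.get_params()
        assert params["hard_threshold_coeff"] == 0.1


class TestDiagnostics:
    def test_constant_image_energy_at_dc(self):
        spec = log_spectrum(np.full((16, 16), 0.3, np.float32))
        dc = np.unravel_index(np.argmax(spec), spec.shape)
        assert dc == (8, 8)
        off_dc = spec.copy()
        off_dc[8, 8] = 0
        assert off_dc.max() < 1e-4

    def test_horizontal_sinusoid_peak_pair(self):
        h = w = 32
        f = 5
        x = np.arange(w)
        img = (0.5 + 0.4 * np.sin(2 * np.pi * f * x / w))[None, :].repeat(h, 0)
        spec = log_spectrum(img.astype(np.float32))
        spec_no_dc = spec.copy()
        spec_no_dc[h // 2, w // 2] = 0
        peaks = np.argsort(spec_no_dc.ravel())[-2:]
        coords = sorted(np.unravel_index(p, spec.shape) for p in peaks)
        assert coords == [(h // 2, w // 2 - f), (h // 2, w // 2 + f)]

    def test_psnr_closed_forms(self, rng):
        a = rng.random((8, 8)).astype(np.float32)
        assert psnr(a, a) == PSNR_INF
        b = np.zeros((8, 8)); c = np.full((8, 8), 0.1)
        assert psnr(b, c) == pytest.approx(20.0, abs=1e-5)
        d = rng.random((8, 8)).astype(np.float32)
        mse = np.mean((a.astype(np.float64) - d.astype(np.float64)) ** 2)
        assert psnr(a, d) == pytest.approx(10 * np.log10(1 / mse), rel=1e-9)

    def test_psnr_shape_mismatch(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((2, 2)), np.zeros((3, 3)))
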