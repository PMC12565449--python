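"""LoG kernel correctness and first-order statistics."""

import math

import numpy as np
import pytest

from nodulefusion.dataio import CTVolume, NoduleMask
from nodulefusion.radiomics3d import (FEATURE_NAMES, SSF_VALUES,
                                      build_log_kernel, extract_radiomics,
                                      filter_slice, histogram_stats,
                                      log_closed_form)

from _oracles import naive_log_value, naive_radiomics, naive_stats


class TestKernel:
    def test_closed_form_at_origin(self):
        k = build_log_kernel(sigma_mm=2.0, in_plane_spacing_mm=1.0)
        assert k.sigma_px == 2.0
        r = k.truncation_radius_px
        assert k.raw[r, r] == pytest.approx(-1.0 / (16 * math.pi), rel=1e-12)

    def test_closed_form_everywhere(self):
        k = build_log_kernel(sigma_mm=3.0, in_plane_spacing_mm=1.0)
        r = k.truncation_radius_px
        for (i, j) in [(0, 0), (1, 2), (-3, 5), (r, -r), (0, r)]:
            assert k.raw[r + i, r + j] == pytest.approx(
                naive_log_value(i, j, 3.0), rel=1e-12)

    def test_zero_crossing_ring(self):
        # x^2 + y^2 = 2 sigma^2 is an exact root of the closed form
        sigma = math.sqrt(2.0)   # ring hits integer offsets (0, +-2), (+-2, 0)
        k = build_log_kernel(sigma, 1.0)
        r = k.truncation_radius_px
        assert k.raw[r, r + 2] == pytest.approx(0.0, abs=1e-15)
        assert k.raw[r - 2, r] == pytest.approx(0.0, abs=1e-15)
        assert log_closed_form(2.0, 0.0, sigma) == pytest.approx(0.0,
                                                                 abs=1e-15)

    def test_zero_sum_and_symmetry(self):
        for ssf in (2, 3, 4, 5, 6):
            k = build_log_kernel(float(ssf), 0.7)
            assert abs(k.kernel.sum()) <= 1e-12
            assert np.allclose(k.kernel, k.kernel[::-1, ::-1])
            assert np.allclose(k.kernel, k.kernel.T)
            r = k.truncation_radius_px
            assert k.kernel[r, r] == k.kernel.min()
            assert k.kernel.shape == (2 * r + 1, 2 * r + 1)

    def test_scale_below_resolution(self):
        with pytest.raises(ValueError, match="below resolution"):
            build_log_kernel(0.3, 0.7)

    def test_matches_gaussian_laplacian_construction(self):
        """The sampled closed form agrees with a discrete Gaussian convolved
        with the 5-point discrete Laplacian; the residual is the O(1/sigma^2)
        discretisation error of the Laplacian stencil, so it shrinks
        quadratically with scale."""
        from scipy.signal import convolve2d

        errs = {}
        for sigma in (2.0, 3.0, 4.0):
            k = build_log_kernel(sigma, 1.0)
            r = k.truncation_radius_px
            off = np.arange(-r - 1, r + 2)
            gauss = (1.0 / (2 * math.pi * sigma**2)
                     * np.exp(-(off[:, None]**2 + off[None, :]**2)
                              / (2 * sigma**2)))
            lap = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)
            disc = convolve2d(gauss, lap, mode="valid")
            scale = np.abs(k.raw).max()
            errs[sigma] = np.abs(disc - k.raw).max() / scale
            assert errs[sigma] < 0.3 / sigma**2   # second-order stencil error
        assert errs[4.0] < errs[2.0] * (2.0 / 4.0) ** 2 * 1.5


class TestFilter:
    def test_constant_image_zero_response(self):
        k = build_log_kernel(2.0, 1.0)
        out = filter_slice(np.full((40, 40), 123.4), k)
        assert np.abs(out).max() < 1e-9

    def test_ssf0_identity(self):
        img = np.random.default_rng(0).normal(size=(32, 32))
        assert np.array_equal(filter_slice(img, None), img)

    def test_impulse_response_is_kernel(self):
        k = build_log_kernel(2.0, 1.0)
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        out = filter_slice(img, k)
        r = k.truncation_radius_px
        window = out[32 - r:32 + r + 1, 32 - r:32 + r + 1]
        # the kernel is point-symmetric: convolution == correlation
        assert np.allclose(window, k.kernel, atol=1e-10)

    def test_kernel_larger_than_slice(self):
        k = build_log_kernel(6.0, 0.7)   # 71x71
        with pytest.raises(ValueError, match="larger than slice"):
            filter_slice(np.zeros((32, 32)), k)


class TestHistogramStats:
    def test_two_point_symmetric_sample(self):
        s = histogram_stats(np.array([-1.0, 1.0]))
        assert (s.mean, s.sd, s.mpp) == (0.0, 1.0, 1.0)
        assert s.entropy == pytest.approx(1.0)
        assert s.skewness == 0.0
        assert s.kurtosis == pytest.approx(-2.0)

    def test_constant_sample_flagged(self):
        s = histogram_stats(np.full(10, 3.3))
        assert (s.sd, s.entropy, s.skewness, s.kurtosis) == (0, 0, 0, 0)
        assert "zero_sd_moments" in s.flags

    def test_no_positive_values_flagged(self):
        s = histogram_stats(np.array([-2.0, -1.0]))
        assert s.mpp == 0.0
        assert "mpp_no_positive" in s.flags

    def test_normal_draws_match_bruteforce_and_theory(self):
        v = np.random.default_rng(123).standard_normal(10_000)
        s = histogram_stats(v)
        oracle = naive_stats(v)
        for key in ("mean", "sd", "entropy", "mpp", "skewness", "kurtosis"):
            assert getattr(s, key) == pytest.approx(oracle[key], abs=1e-12)
        assert abs(s.skewness) < 0.1
        assert abs(s.kurtosis) < 0.1
        assert abs(s.mean) < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            histogram_stats(np.array([]))


def _random_masked_volume(rng, shape=(8, 32, 32)):
    vox = rng.normal(-600, 150, shape)
    mask = np.zeros(shape, dtype=np.uint8)
    z0 = rng.integers(1, shape[0] - 4)
    mask[z0:z0 + 3, 10:22, 8:24] = (rng.random((3, 12, 16)) > 0.4)
    if mask.sum() == 0:
        mask[z0, 12, 12] = 1
    vol = CTVolume(voxels=vox, spacing_mm=(2.0, 2.0, 2.0), case_id="r")
    return vol, NoduleMask(mask=mask, case_id="r")


class TestExtractRadiomics:
    def test_vector_length_and_key_order(self, case_g1):
        volume, mask, _ = case_g1
        vec = extract_radiomics(volume, mask)
        assert len(vec.values) == 36
        assert vec.names == FEATURE_NAMES
        assert FEATURE_NAMES[0] == "ssf0_mean"
        assert FEATURE_NAMES[-1] == "ssf6_kurtosis"

    def test_ssf0_mean_is_plain_mask_mean(self, case_g1):
        volume, mask, _ = case_g1
        vec = extract_radiomics(volume, mask)
        expected = volume.voxels[mask.mask.astype(bool)].mean()
        assert vec["ssf0_mean"] == expected

    def test_constant_shift_invariance_of_filtered_scales(self, rng):
        vol, mask = _random_masked_volume(rng)
        v1 = extract_radiomics(vol, mask)
        shifted = CTVolume(voxels=vol.voxels + 100.0,
                           spacing_mm=vol.spacing_mm, case_id="s")
        v2 = extract_radiomics(shifted, mask)
        for ssf in (2, 3, 4, 5, 6):
            for stat in ("mean", "sd", "entropy", "mpp", "skewness",
                         "kurtosis"):
                key = f"ssf{ssf}_{stat}"
                assert v2[key] == pytest.approx(v1[key], abs=1e-6), key
        assert v2["ssf0_mean"] == pytest.approx(v1["ssf0_mean"] + 100.0)
        assert v2["ssf0_sd"] == pytest.approx(v1["ssf0_sd"], abs=1e-9)

    def test_mask_locality(self, rng):
        vol, mask = _random_masked_volume(rng)
        v1 = extract_radiomics(vol, mask)
        # largest kernel radius at 2 mm spacing: ceil(4 * 6/2) = 12 px
        from scipy.ndimage import binary_dilation
        guard = binary_dilation(mask.mask.astype(bool),
                                np.ones((1, 25, 25), dtype=bool))
        far = ~guard
        assert far.any()
        vox = vol.voxels.copy()
        vox[far] += rng.normal(0, 300, far.sum())
        v2 = extract_radiomics(CTVolume(voxels=vox, spacing_mm=vol.spacing_mm,
                                        case_id="far"), mask)
        np.testing.assert_allclose(v2.values, v1.values, rtol=1e-9)

    def test_anisotropic_spacing_rejected(self, rng):
        vol, mask = _random_masked_volume(rng)
        bad = CTVolume(voxels=vol.voxels, spacing_mm=(2.0, 1.0, 2.0),
                       case_id="a")
        with pytest.raises(ValueError, match="anisotropic"):
            extract_radiomics(bad, mask)

    def test_scale_monotonicity_of_injected_texture(self, separable_spec):
        """Texture injected at the 6 mm Gaussian scale raises the SSF=6 band
        SD proportionally more than the SSF=2 band SD (averaged over 50
        phantoms).  The comparison is relative to each band's baseline: the
        fine band has a far larger baseline SD, so absolute increments are
        not comparable across bands."""
        from scipy.ndimage import distance_transform_edt, gaussian_filter
        from nodulefusion.phantom import case_seed, generate_case_full

        rng = np.random.default_rng(0)
        d2, d6 = [], []
        for i in range(50):
            v, m, _ = generate_case_full(separable_spec, "G1",
                                         case_seed(9, "G1", i))
            base = extract_radiomics(v, m, ssf_values=(2, 6))
            noise = gaussian_filter(rng.standard_normal(v.voxels.shape),
                                    (0, 6 / 0.7, 6 / 0.7))
            noise /= noise.std()
            weight = np.zeros(v.voxels.shape)
            for k in np.flatnonzero(m.mask.any(axis=(1, 2))):
                dist = distance_transform_edt(~m.mask[k].astype(bool))
                weight[k] = gaussian_filter((dist <= 12 / 0.7).astype(float),
                                            3.0)
            vox = np.clip(v.voxels + 60.0 * noise * weight, -1024, 400)
            after = extract_radiomics(
                CTVolume(voxels=vox, spacing_mm=v.spacing_mm, case_id="t"),
                m, ssf_values=(2, 6))
            d2.append(after["ssf2_sd"] / base["ssf2_sd"])
            d6.append(after["ssf6_sd"] / base["ssf6_sd"])
        assert np.mean(d6) > np.mean(d2) > 1.0

    def test_bruteforce_oracle_small(self, rng):
        """All 36 features match naive per-pixel convolution plus direct
        moment formulas (3 random volumes here; the wider sweep runs in the
        acceptance suite)."""
        for _ in range(3):
            vol, mask = _random_masked_volume(rng)
            got = extract_radiomics(vol, mask).values
            want = naive_radiomics(vol.voxels, mask.mask, 2.0)
            np.testing.assert_allclose(got, want, rtol=1e-6, atol=1e-9)
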