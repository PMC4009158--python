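"""Noise estimation, wavelet transforms, bias correction, bilateral and
Wiener stages, and the assembled denoising pipeline."""

import numpy as np
import pytest

import ricewave as rw
from ricewave.wavelet_filter import Rect


def brute_force_bilateral(arr, rho_d, rho_r, window):
    """Direct double-loop evaluation of the normalized bilateral sum."""
    h, w = arr.shape
    half = window // 2
    out = np.empty_like(arr)
    for i in range(h):
        for j in range(w):
            num = den = 0.0
            for y in range(max(0, i - half), min(h, i + half + 1)):
                for x in range(max(0, j - half), min(w, j + half + 1)):
                    ws = np.exp(-((i - y) ** 2 + (j - x) ** 2) / (2 * rho_d**2))
                    wr = np.exp(-((arr[i, j] - arr[y, x]) ** 2) / (2 * rho_r**2))
                    num += ws * wr * arr[y, x]
                    den += ws * wr
            out[i, j] = num / den
    return out


class TestBackgroundSigma:
    def test_direct_formula(self):
        img = np.ones((4, 4))
        # 2x2 patch of ones: sqrt(4 / (2*4)) = sqrt(0.5)
        assert rw.estimate_background_sigma(img, Rect(0, 0, 2, 2)) == pytest.approx(
            np.sqrt(0.5)
        )

    def test_rayleigh_patch_recovers_sigma(self, rng):
        sigma = 5.0
        patch = np.hypot(rng.normal(0, sigma, (100, 100)), rng.normal(0, sigma, (100, 100)))
        est = rw.estimate_background_sigma(patch, Rect(0, 0, 100, 100))
        # var of I^2 for Rayleigh: E[I^4] - (E[I^2])^2 = 4 sigma^4
        se = 2 * sigma**2 / np.sqrt(patch.size)
        # delta method: d sigma / d E[I^2] = 1/(4 sigma)
        assert abs(est - sigma) < 3 * se / (4 * sigma)

    def test_zero_patch(self):
        assert rw.estimate_background_sigma(np.zeros((8, 8)), Rect(0, 0, 4, 4)) == 0.0

    def test_out_of_bounds_patch(self):
        with pytest.raises(ValueError):
            rw.estimate_background_sigma(np.zeros((8, 8)), Rect(6, 6, 4, 4))

    def test_too_small_patch(self):
        with pytest.raises(ValueError):
            rw.estimate_background_sigma(np.zeros((8, 8)), Rect(0, 0, 1, 2))


class TestDecompose:
    def test_haar_scaling_of_constant_image(self):
        dec = rw.decompose(np.ones((32, 32)), "haar", 3)
        # level-3 Haar scaling coefficient of a constant-1 image is
        # (1/2^3) * sum over the 8x8 block = 64/8 = 8
        assert dec.scaling.shape == (4, 4)
        assert np.allclose(dec.scaling, 8.0, atol=1e-12)

    def test_haar_scaling_of_delta_image(self):
        img = np.zeros((16, 16))
        img[0, 0] = 1.0
        dec = rw.decompose(img, "haar", 3)
        expected = np.zeros((2, 2))
        expected[0, 0] = 1.0 / 8.0
        assert np.allclose(dec.scaling, expected, atol=1e-12)

    @pytest.mark.parametrize("basis,level", [("haar", 3), ("db4", 4)])
    def test_perfect_reconstruction(self, rng, basis, level):
        img = rng.uniform(0, 88, (64, 64))
        rec = rw.reconstruct(rw.decompose(img, basis, level))
        assert np.max(np.abs(rec - img)) < 1e-10 * max(1.0, np.max(np.abs(img)))

    def test_perfect_reconstruction_non_dyadic_shape(self, rng):
        img = rng.uniform(0, 88, (50, 41))  # requires padding then cropping
        rec = rw.reconstruct(rw.decompose(img, "db4", 4))
        assert rec.shape == img.shape
        assert np.max(np.abs(rec - img)) < 1e-9

    def test_unknown_basis(self):
        with pytest.raises(ValueError):
            rw.decompose(np.ones((16, 16)), "sym5", 2)


class TestBiasCorrection:
    def test_round_trip_composition(self):
        sigma, level, x = 2.0, 3, 10.0
        c = sigma * 2**level * rw.rice_mean_ratio(x)
        out = rw.correct_scaling_bias(np.array([[c]]), sigma, level, rw.DEFAULT_PARAMS)
        assert out[0, 0] == pytest.approx(sigma * 2**level * x, abs=0.05 * sigma * 2**level)

    def test_zero_maps_to_zero(self):
        out = rw.correct_scaling_bias(np.zeros((3, 3)), 1.5, 3, rw.DEFAULT_PARAMS)
        assert np.all(out == 0.0)

    def test_homogeneity_in_coefficient_and_sigma(self, rng):
        c = rng.uniform(0, 100, (5, 5))
        one = rw.correct_scaling_bias(c, 2.0, 3, rw.DEFAULT_PARAMS)
        two = rw.correct_scaling_bias(2 * c, 4.0, 3, rw.DEFAULT_PARAMS)
        assert np.allclose(two, 2 * one, rtol=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            rw.correct_scaling_bias(np.ones((2, 2)), 0.0, 3, rw.DEFAULT_PARAMS)


class TestBilateral:
    def test_constant_array_is_fixed_point(self):
        arr = np.full((9, 9), 7.0)
        assert np.allclose(rw.bilateral(arr, 5.0, 1.0, 3), 7.0, atol=1e-12)

    def test_matches_brute_force(self, rng):
        arr = rng.uniform(0, 10, (5, 5))
        got = rw.bilateral(arr, rho_d=2.0, rho_r=3.0, window=3)
        want = brute_force_bilateral(arr, 2.0, 3.0, 3)
        assert np.max(np.abs(got - want)) < 1e-12

    def test_step_edge_preserved_when_range_scale_small(self):
        step = np.zeros((8, 16))
        step[:, 8:] = 100.0
        out = rw.bilateral(step, rho_d=5.0, rho_r=1.0, window=5)
        assert np.max(np.abs(out - step)) < 1.0  # rho_r << step height

    def test_output_within_input_range(self, rng):
        arr = rng.uniform(-3, 9, (12, 12))
        out = rw.bilateral(arr, 2.0, 0.5, 7)
        assert out.min() >= arr.min() - 1e-12
        assert out.max() <= arr.max() + 1e-12

    def test_nonpositive_scales_rejected(self):
        with pytest.raises(ValueError):
            rw.bilateral(np.ones((4, 4)), 0.0, 1.0, 3)
        with pytest.raises(ValueError):
            rw.bilateral(np.ones((4, 4)), 1.0, -1.0, 3)
        with pytest.raises(ValueError):
            rw.bilateral(np.ones((4, 4)), 1.0, 1.0, 4)


class TestWienerShrink:
    def test_local_energy_at_threshold_zeroes(self):
        sigma = 2.0
        band = np.full((8, 8), sigma)  # local E[d^2] = sigma^2 < tau sigma^2
        (out,) = rw.wiener_shrink([(band, band, band)], sigma, tau=2.0)
        for b in out:
            assert np.all(b == 0.0)

    def test_four_sigma_energy_halves(self):
        sigma = 1.5
        band = np.full((8, 8), 2 * sigma)  # E[d^2] = 4 sigma^2, tau=2 -> alpha=1/2
        (out,) = rw.wiener_shrink([(band, band, band)], sigma, tau=2.0)
        for b in out:
            assert np.allclose(b, sigma, atol=1e-12)

    def test_zero_sigma_is_identity(self, rng):
        band = rng.normal(0, 3, (8, 8))
        (out,) = rw.wiener_shrink([(band, band, band)], 0.0)
        for b in out:
            assert np.array_equal(b, band)

    def test_energy_never_increases(self, rng):
        details = [tuple(rng.normal(0, 2, (16, 16)) for _ in range(3)) for _ in range(2)]
        out = rw.wiener_shrink(details, sigma=1.0, tau=2.0)
        for lvl_in, lvl_out in zip(details, out):
            for b_in, b_out in zip(lvl_in, lvl_out):
                assert np.sum(b_out**2) <= np.sum(b_in**2)
                # weights in [0, 1)
                ratio = np.abs(b_out) / np.maximum(np.abs(b_in), 1e-300)
                assert np.all(ratio < 1.0)

    def test_tau_below_one_rejected(self):
        with pytest.raises(ValueError):
            rw.wiener_shrink([(np.ones((4, 4)),) * 3], 1.0, tau=0.5)


class TestDenoisePipeline:
    def test_noise_free_input_passes_through(self, phantom128):
        out = rw.denoise(phantom128)  # zero corner patch -> sigma = 0
        assert rw.rmse(phantom128, out) < 1e-6

    def test_improves_ssim_and_rmse_under_noise(self, phantom128):
        noisy = rw.add_rician_noise(phantom128, 5.0, 99)
        den = rw.denoise(noisy)
        assert rw.ssim(phantom128, den) > rw.ssim(phantom128, noisy)
        assert rw.rmse(phantom128, den) < rw.rmse(phantom128, noisy)

    def test_output_nonnegative(self, phantom128):
        noisy = rw.add_rician_noise(phantom128, 12.0, 7)
        assert np.all(rw.denoise(noisy) >= 0.0)

    def test_bilateral_switch_changes_output(self, phantom128):
        noisy = rw.add_rician_noise(phantom128, 5.0, 5)
        on = rw.denoise(noisy, rw.FilterConfig(bilateral_enabled=True))
        off = rw.denoise(noisy, rw.FilterConfig(bilateral_enabled=False))
        assert not np.allclose(on, off)
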