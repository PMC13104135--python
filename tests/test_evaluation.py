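"""Quality metrics: exact oracles for entropy / GLCM / DoG / SNR algebra
and the full-reference metrics."""

import numpy as np
import pytest
from skimage.feature import graycomatrix, graycoprops

from emalign import (EvalParams, SliceStack, difference_image, dog_pyramid,
                     entropy, evaluate_stack, glcm_contrast, laplacian_filter,
                     reference_metrics, snr)
from emalign.evaluation import (bilateral_split, dice, hausdorff,
                                mutual_information, ncc, saturating_quantize,
                                ssim)


class TestDifferenceImage:
    def test_identical_slices_zero(self, textured_slice):
        assert not difference_image(textured_slice, textured_slice).any()

    def test_antisymmetry_and_elementwise(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        d = difference_image(a, b)
        np.testing.assert_array_equal(d, b - a)
        np.testing.assert_array_equal(difference_image(b, a), -d)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            difference_image(np.zeros((4, 4)), np.zeros((5, 4)))


class TestLaplacian:
    def test_constant_zero(self):
        assert not laplacian_filter(np.full((16, 16), 2.5)).any()

    def test_unit_impulse_kernel(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        lap = laplacian_filter(img)
        assert lap[4, 4] == -4.0
        for r, c in ((3, 4), (5, 4), (4, 3), (4, 5)):
            assert lap[r, c] == 1.0

    def test_linear_ramp_zero_interior(self):
        rr, cc = np.meshgrid(np.arange(16.0), np.arange(16.0), indexing="ij")
        lap = laplacian_filter(2.0 * rr - 3.0 * cc)
        np.testing.assert_allclose(lap[1:-1, 1:-1], 0.0, atol=1e-12)


class TestEntropy:
    def test_constant_image_zero_bits(self):
        assert entropy(np.full((16, 16), 0.7)) == 0.0

    def test_two_level_image_one_bit(self):
        img = np.zeros((16, 16), dtype=np.intp)
        img[:, 8:] = 255
        assert entropy(img) == 1.0

    def test_uniform_histogram_eight_bits(self):
        img = np.arange(256, dtype=np.intp)[None].repeat(256, axis=0)
        assert abs(entropy(img) - 8.0) < 1e-12

    def test_matches_bruteforce_histogram_oracle(self, rng):
        img = rng.random((32, 32))
        q = np.round((img - img.min()) / np.ptp(img) * 255).astype(int)
        counts = np.array([(q == v).sum() for v in range(256)])
        p = counts[counts > 0] / q.size
        assert abs(entropy(img) - (-(p * np.log2(p)).sum())) < 1e-12

    def test_saturating_quantize_fixed_scale(self):
        img = np.array([[-2.0, -1.0], [0.0, 1.0]])
        q = saturating_quantize(img, clip=1.0)
        assert q[0, 0] == 0 and q[0, 1] == 0
        assert q[1, 0] == 128 and q[1, 1] == 255


class TestSnr:
    def test_conservation(self, rng):
        """The noise component is defined as input minus structure, so the
        two components reconstruct the input (to float round-off)."""
        lap = rng.standard_normal((32, 32))
        i_f = bilateral_split(lap)
        i_n = lap - i_f
        np.testing.assert_allclose(i_f + i_n, lap, rtol=0, atol=1e-12)

    def test_smooth_structure_beats_noise(self, rng):
        rr, cc = np.meshgrid(np.arange(64.0), np.arange(64.0), indexing="ij")
        smooth = np.sin(2 * np.pi * rr / 32) * np.cos(2 * np.pi * cc / 32)
        noise = rng.standard_normal((64, 64))
        noise *= smooth.std() / noise.std()
        assert snr(smooth) > snr(noise)

    def test_zero_image_infinite_sentinel(self):
        assert snr(np.zeros((16, 16))) == float("inf")


class TestDogPyramid:
    def test_constant_input_zero_layers(self):
        for layer in dog_pyramid(np.full((32, 32), 1.0)):
            np.testing.assert_allclose(layer, 0.0, atol=1e-12)

    def test_telescoping_identity(self, rng):
        from scipy.ndimage import gaussian_filter
        lap = rng.standard_normal((64, 64))
        sigmas = EvalParams().dog_sigmas
        layers = dog_pyramid(lap, sigmas)
        assert len(layers) == 4
        total = sum(layers)
        expected = gaussian_filter(lap, sigmas[0]) - gaussian_filter(lap, sigmas[-1])
        np.testing.assert_allclose(total, expected, atol=1e-10)

    def test_impulse_matches_analytic_gaussian(self):
        n = 65
        img = np.zeros((n, n))
        img[n // 2, n // 2] = 1.0
        sigmas = (1.0, 2.0)
        layer = dog_pyramid(img, sigmas)[0]
        rr, cc = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2,
                             indexing="ij")
        r2 = rr ** 2 + cc ** 2
        analytic = (np.exp(-r2 / 2.0) / (2 * np.pi)
                    - np.exp(-r2 / 8.0) / (8 * np.pi))
        assert np.abs(layer - analytic).max() < 1e-3

    def test_non_increasing_sigmas_rejected(self):
        with pytest.raises(ValueError):
            dog_pyramid(np.zeros((8, 8)), (1.0, 1.0, 2.0))


class TestGlcmContrast:
    def test_constant_image_zero(self):
        assert glcm_contrast(np.full((16, 16), 0.5)) == 0.0

    def test_unit_stripes_horizontal_offset(self):
        img = np.zeros((8, 8))
        img[:, 1::2] = 1.0
        con = glcm_contrast(img, levels=2, offsets=[(0, 1)])
        assert con == 1.0  # every horizontal pair differs by exactly 1 level

    def test_matches_bruteforce_pair_enumeration(self, rng):
        img = rng.random((8, 8))
        levels = 8
        q = np.round((img - img.min()) / np.ptp(img) * (levels - 1)).astype(int)
        for offset in [(0, 1), (1, 1), (1, 0), (1, -1)]:
            dr, dc = offset
            counts = np.zeros((levels, levels))
            h, w = q.shape
            for r in range(h):
                for c in range(w):
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w:
                        counts[q[r, c], q[r2, c2]] += 1
                        counts[q[r2, c2], q[r, c]] += 1
            counts /= counts.sum()
            k = np.arange(levels)
            want = ((k[:, None] - k[None, :]) ** 2 * counts).sum()
            got = glcm_contrast(img, levels=levels, offsets=[offset])
            assert abs(got - want) < 1e-12

    def test_cross_check_against_skimage(self, rng):
        img = rng.integers(0, 16, size=(32, 32))
        scaled = img / 15.0
        got = glcm_contrast(scaled, levels=16, offsets=[(0, 1)])
        P = graycomatrix(img.astype(np.uint8), distances=[1], angles=[0],
                         levels=16, symmetric=True, normed=True)
        want = graycoprops(P, "contrast")[0, 0]
        assert abs(got - want) < 1e-10


class TestEvaluateStack:
    def test_identical_slices_degenerate(self, textured_slice):
        stack = SliceStack(np.repeat(textured_slice[None], 3, axis=0))
        report = evaluate_stack(stack)
        assert (report.per_pair["entropy"] == 0).all()
        for k in range(4):
            assert (report.per_pair[f"con_{k}"] == 0).all()

    def test_row_count_and_outputs(self, phantom_stack, tmp_path):
        report = evaluate_stack(SliceStack(phantom_stack.data[:5]))
        assert len(report.per_pair) == 4
        report.to_csv(tmp_path / "pairs.csv")
        payload = report.to_json(tmp_path / "report.json")
        assert "mean_entropy" in payload["summary"]
        assert (tmp_path / "pairs.csv").exists()

    def test_needs_two_slices(self, textured_slice):
        with pytest.raises(ValueError):
            evaluate_stack(SliceStack(textured_slice[None]))


class TestReferenceMetrics:
    def test_identical_stacks_perfect_scores(self, phantom_stack):
        data = phantom_stack.data[:3]
        labels = (data > 0.5).astype(int)
        df = reference_metrics(SliceStack(data), SliceStack(data.copy()),
                               labels, labels.copy())
        assert np.allclose(df["ssim"], 1.0)
        assert np.allclose(df["ncc"], 1.0)
        assert np.allclose(df["dice"], 1.0)
        assert np.allclose(df["hausdorff"], 0.0)

    def test_inverted_image_ncc_minus_one(self, textured_slice):
        assert abs(ncc(textured_slice, 1.0 - textured_slice) + 1.0) < 1e-12

    def test_dice_counting_oracle(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, :3] = True          # |A| = 3
        b[0, 1:4] = True         # |B| = 3, overlap = 2
        assert abs(dice(a, b) - 2 * 2 / 6) < 1e-12

    def test_empty_mask_conventions(self):
        empty = np.zeros((4, 4), bool)
        full = np.ones((4, 4), bool)
        assert dice(empty, empty) == 1.0
        assert dice(empty, full) == 0.0
        assert np.isnan(hausdorff(empty, full))

    def test_hausdorff_known_distance(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[3, 4] = True
        assert abs(hausdorff(a, b) - 5.0) < 1e-12

    def test_mutual_information_drops_when_shuffled(self, textured_slice, rng):
        flat = textured_slice.ravel().copy()
        rng.shuffle(flat)
        shuffled = flat.reshape(textured_slice.shape)
        assert (mutual_information(textured_slice, textured_slice)
                > mutual_information(textured_slice, shuffled))

    def test_ssim_of_noisy_copy_below_one(self, textured_slice, rng):
        noisy = np.clip(textured_slice + rng.normal(0, 0.05,
                                                    textured_slice.shape), 0, 1)
        assert 0.2 < ssim(textured_slice, noisy) < 1.0
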