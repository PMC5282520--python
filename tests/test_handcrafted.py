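import numpy as np
import pytest

from lensbench.features.handcrafted import (
    color_moments,
    color_texture_vector,
    disperse_gradient,
    gradient_image,
    graygradient_features,
    graytone_features,
    graytone_matrix,
)
from lensbench.prep import quantize_gray

from .oracles import color_moments_loop, ggcm_loop, glcm_enumerate, haralick_loop, sobel_loop


class TestColorMoments:
    def test_constant_image(self):
        img = np.full((5, 5, 3), 100, dtype=np.uint8)
        np.testing.assert_allclose(color_moments(img).values, [100, 0, 0] * 3)

    def test_two_point_symmetric_mass(self):
        img = np.zeros((1, 2, 3), dtype=np.uint8)
        img[0, 1] = 200
        fv = color_moments(img)
        for c in range(3):
            assert fv.values[3 * c] == pytest.approx(100)
            assert fv.values[3 * c + 1] == pytest.approx(100)

    def test_matches_loop_oracle(self, rng):
        for _ in range(5):
            img = rng.integers(0, 256, size=(8, 8, 3)).astype(np.uint8)
            np.testing.assert_allclose(
                color_moments(img).values, color_moments_loop(img), rtol=1e-9
            )


class TestGraytoneMatrix:
    def test_constant_2x2_symmetric_counting(self):
        img = np.full((2, 2), 5, dtype=np.uint8)
        m = graytone_matrix(img, d=1, theta=0, levels=8)
        assert m.counts[5, 5] == 4  # 2 adjacent pairs x 2 orderings
        assert m.counts.sum() == 4

    @pytest.mark.parametrize("theta", [0, 45, 90, 135])
    def test_toy_image_matches_enumeration(self, theta):
        img = np.array([[0, 0, 1], [0, 1, 1], [1, 1, 1]], dtype=np.uint8)
        m = graytone_matrix(img, d=1, theta=theta, levels=2)
        np.testing.assert_array_equal(m.counts, glcm_enumerate(img, 1, theta, 2))

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="no pixel pairs"):
            graytone_matrix(np.zeros((1, 1), dtype=np.uint8), d=1, theta=0)

    def test_symmetry_and_marginals(self, rng):
        img = rng.integers(0, 4, size=(7, 9)).astype(np.uint8)
        m = graytone_matrix(img, d=1, theta=45, levels=4)
        np.testing.assert_array_equal(m.counts, m.counts.T)
        np.testing.assert_array_equal(m.counts.sum(axis=0), m.counts.sum(axis=1))


class TestGraytoneFeatures:
    def test_constant_image_degenerate_conventions(self):
        fv = graytone_features(np.full((6, 6), 99, dtype=np.uint8))
        named = dict(zip(fv.names, fv.values))
        assert named["graytone_asm"] == pytest.approx(1.0)
        assert named["graytone_contrast"] == pytest.approx(0.0)
        assert named["graytone_entropy"] == pytest.approx(0.0)
        assert named["graytone_correlation"] == 0.0
        assert np.all(np.isfinite(fv.values))

    def test_length_is_14(self, rng):
        img = rng.integers(0, 256, size=(10, 10)).astype(np.uint8)
        assert len(graytone_features(img)) == 14

    def test_matches_formula_oracle(self, random_gray_images):
        for img in random_gray_images:
            q = quantize_gray(img, 8)
            total = np.zeros((8, 8), dtype=np.int64)
            for theta in (0, 45, 90, 135):
                total += graytone_matrix(q, 1, theta, levels=8).counts
            p = total / total.sum()
            np.testing.assert_allclose(
                graytone_features(img, d=1, levels=8).values,
                haralick_loop(p),
                rtol=1e-9,
                atol=1e-12,
            )

    def test_transpose_invariance(self, rng):
        img = rng.integers(0, 256, size=(9, 12)).astype(np.uint8)
        a = graytone_features(img).values
        b = graytone_features(img.T.copy()).values
        np.testing.assert_allclose(a, b, rtol=1e-8, atol=1e-10)


class TestGradientImage:
    def test_constant_is_zero(self):
        g = gradient_image(np.full((5, 5), 44, dtype=np.uint8))
        assert np.all(g == 0)
        assert np.all(disperse_gradient(g, 10) == 0)

    def test_vertical_step_edge_localized(self):
        img = np.zeros((5, 8), dtype=np.uint8)
        img[:, 4:] = 200
        levels = disperse_gradient(gradient_image(img), 10)
        assert np.all(levels[:, [3, 4]] == 9)
        assert np.all(levels[:, [0, 1, 6, 7]] == 0)

    def test_matches_convolution_oracle(self, random_gray_images):
        for img in random_gray_images:
            np.testing.assert_allclose(gradient_image(img), sobel_loop(img), rtol=1e-9)

    def test_too_small_raises(self):
        with pytest.raises(ValueError, match="too small"):
            gradient_image(np.zeros((2, 5), dtype=np.uint8))


class TestGraygradientFeatures:
    def test_constant_image(self):
        fv = graygradient_features(np.full((6, 6), 50, dtype=np.uint8))
        named = dict(zip(fv.names, fv.values))
        assert named["graygradient_energy"] == pytest.approx(1.0)
        assert named["graygradient_mixed_entropy"] == pytest.approx(0.0)
        assert named["graygradient_gradient_mean"] == pytest.approx(0.0)
        assert np.all(np.isfinite(fv.values))

    def test_length_is_15(self, rng):
        img = rng.integers(0, 256, size=(6, 6)).astype(np.uint8)
        assert len(graygradient_features(img)) == 15

    def test_matches_formula_oracle(self, random_gray_images):
        for img in random_gray_images:
            gray_q = quantize_gray(img, 16).astype(int)
            grad_q = disperse_gradient(gradient_image(img), 10)
            np.testing.assert_allclose(
                graygradient_features(img, gradient_levels=10, gray_levels=16).values,
                ggcm_loop(gray_q, grad_q, 16, 10),
                rtol=1e-9,
                atol=1e-12,
            )

    def test_probabilities_sum_to_one(self, rng):
        from lensbench.features.handcrafted import graygradient_matrix

        img = rng.integers(0, 256, size=(8, 8)).astype(np.uint8)
        assert graygradient_matrix(img).probabilities().sum() == pytest.approx(1.0)


class TestColorTextureVector:
    def test_length_and_blocks(self, small_dataset):
        fv = color_texture_vector(small_dataset.images[0])
        assert len(fv) == 38
        assert fv.block_map == {"color": (0, 9), "graytone": (9, 23), "graygradient": (23, 38)}

    def test_deterministic(self, small_dataset):
        img = small_dataset.images[1]
        a = color_texture_vector(img).values
        b = color_texture_vector(img.copy()).values
        np.testing.assert_array_equal(a, b)

    def test_constant_image(self):
        img = np.full((8, 8, 3), 77, dtype=np.uint8)
        fv = color_texture_vector(img)
        np.testing.assert_allclose(fv.block("color"), [77, 0, 0] * 3)
        named = dict(zip(fv.names, fv.values))
        assert named["graytone_entropy"] == 0.0
        assert named["graygradient_mixed_entropy"] == 0.0
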