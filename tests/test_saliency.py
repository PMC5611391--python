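"""GBVS saliency: masking, Markov equilibria vs dense eigen-oracle,
full maps, and the contour-saliency score."""

import numpy as np
import pytest

from delinmetrics import (
    Delineation,
    SaliencyConfig,
    compute_saliency,
    contour_saliency_score,
    gbvs_activation,
    gbvs_normalize,
    mask_non_brain,
    rasterize_boundary,
)


def dense_equilibrium(weights):
    """Independent oracle: stationary vector of the column-normalized
    chain from a dense eigen-decomposition."""
    col = weights.sum(axis=0)
    n = weights.shape[0]
    M = weights / np.where(col == 0, 1.0, col)
    M[:, col == 0] = 1.0 / n
    vals, vecs = np.linalg.eig(M)
    v = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
    v = np.abs(v)
    return v / v.sum()


def activation_weights(f, sigma):
    """The documented edge weights, assembled independently."""
    h, w = f.shape
    ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    kernel = np.exp(-d2 / (2 * sigma**2))
    flat = f.ravel()
    return np.abs(flat[None, :] - flat[:, None]) * kernel


class TestMasking:
    def test_all_true_mask_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((16, 16))
        out = mask_non_brain(img, np.ones((16, 16), dtype=bool))
        assert np.allclose(out, img)

    def test_constant_image_unchanged(self):
        img = np.full((16, 16), 7.0)
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:12, 4:12] = True
        assert np.allclose(mask_non_brain(img, mask), img)

    def test_outside_set_to_inside_mean(self):
        img = np.zeros((8, 8))
        mask = np.zeros((8, 8), dtype=bool)
        mask[2:6, 2:6] = True
        img[mask] = 10.0
        img[0, 0] = 999.0  # bright "skull"
        out = mask_non_brain(img, mask)
        assert out[0, 0] == pytest.approx(10.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mask_non_brain(np.zeros((4, 4)), np.zeros((4, 4), dtype=bool))


class TestEquilibria:
    def test_constant_map_gives_uniform_with_warning(self):
        cfg = SaliencyConfig(map_resolution=8)
        with pytest.warns(UserWarning, match="constant"):
            act = gbvs_activation(np.full((8, 8), 3.0), cfg)
        assert np.allclose(act, 1.0 / 64)

    def test_activation_sums_to_one(self):
        rng = np.random.default_rng(1)
        cfg = SaliencyConfig(map_resolution=8)
        for _ in range(5):
            act = gbvs_activation(rng.random((8, 8)), cfg)
            assert act.sum() == pytest.approx(1.0, abs=1e-9)
            assert (act >= 0).all()

    def test_activation_matches_dense_eigensolver_outlier_map(self):
        # 4x4 map with one outlier pixel: 16-state chain
        f = np.zeros((4, 4))
        f[1, 2] = 1.0
        cfg = SaliencyConfig(map_resolution=4)
        act = gbvs_activation(f, cfg).ravel()
        expected = dense_equilibrium(activation_weights(f, 0.15 * 4))
        assert np.abs(act - expected).max() < 1e-8

    def test_activation_matches_dense_eigensolver_random_256_states(self):
        rng = np.random.default_rng(5)
        f = rng.random((16, 16))
        cfg = SaliencyConfig(map_resolution=16)
        act = gbvs_activation(f, cfg).ravel()
        expected = dense_equilibrium(activation_weights(f, 0.15 * 16))
        assert np.abs(act - expected).max() < 1e-8

    def test_normalize_uniform_fixed_point(self):
        cfg = SaliencyConfig(map_resolution=8)
        uniform = np.full((8, 8), 1.0 / 64)
        assert np.array_equal(gbvs_normalize(uniform, cfg), uniform)

    def test_normalize_preserves_peak_location(self):
        rng = np.random.default_rng(3)
        act = gbvs_activation(rng.random((8, 8)) + np.eye(8) * 2, SaliencyConfig(map_resolution=8))
        out = gbvs_normalize(act, SaliencyConfig(map_resolution=8))
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.unravel_index(out.argmax(), out.shape) == np.unravel_index(
            act.argmax(), act.shape
        )

    def test_normalize_matches_dense_eigensolver(self):
        rng = np.random.default_rng(7)
        a = rng.random((8, 8))
        a /= a.sum()
        cfg = SaliencyConfig(map_resolution=8)
        out = gbvs_normalize(a, cfg).ravel()
        h, w = a.shape
        ii, jj = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
        d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
        kernel = np.exp(-d2 / (2 * (0.15 * w) ** 2))
        weights = a.ravel()[:, None] * kernel
        expected = dense_equilibrium(weights)
        assert np.abs(out - expected).max() < 1e-8


@pytest.fixture(scope="module")
def phantom_slice(small_phantom):
    _, stack, gt = small_phantom
    return stack.images["T1"][7], stack.brain_masks[7], gt.masks[7]


class TestComputeSaliency:
    CFG = SaliencyConfig(map_resolution=16, output_resolution=128)

    def test_output_shape_and_range(self, phantom_slice):
        img, brain, _ = phantom_slice
        smap = compute_saliency(img, brain, self.CFG)
        assert smap.shape == (128, 128)
        assert smap.min() >= 0.0
        assert smap.max() == pytest.approx(1.0)

    def test_zero_outside_brain(self, phantom_slice):
        img, brain, _ = phantom_slice
        smap = compute_saliency(img, brain, self.CFG)
        assert np.all(smap[~brain] == 0.0)

    def test_tumor_more_salient_than_rest_of_brain(self, small_phantom):
        _, stack, gt = small_phantom
        ratios = []
        for k in (6, 7, 8):
            smap = compute_saliency(stack.images["T1"][k], stack.brain_masks[k], self.CFG)
            inside = gt.masks[k]
            outside = stack.brain_masks[k] & ~inside
            ratios.append(smap[inside].mean() / smap[outside].mean())
        assert all(r > 1.0 for r in ratios)

    def test_affine_intensity_invariance(self, phantom_slice):
        img, brain, _ = phantom_slice
        a = compute_saliency(img.astype(float), brain, self.CFG)
        b = compute_saliency(img.astype(float) * 3.0 + 250.0, brain, self.CFG)
        assert np.allclose(a, b, atol=1e-7)

    def test_constant_masked_image_gives_zero_map(self):
        img = np.full((64, 64), 100.0)
        brain = np.zeros((64, 64), dtype=bool)
        brain[8:56, 8:56] = True
        cfg = SaliencyConfig(map_resolution=8, output_resolution=64)
        with pytest.warns(UserWarning):
            smap = compute_saliency(img, brain, cfg)
        assert np.all(smap == 0.0)


class TestContourSaliencyScore:
    def test_uniform_map_counts_boundary_pixels(self):
        smap = np.ones((32, 32))
        d = Delineation("o", "s", 0, np.array([[5, 5], [5, 14], [14, 14], [14, 5]]))
        boundary = rasterize_boundary(d, 32, 32)
        assert contour_saliency_score(smap, boundary) == boundary.sum()

    def test_empty_boundary_scores_zero(self):
        assert contour_saliency_score(np.ones((8, 8)), np.zeros((8, 8), bool)) == 0.0

    def test_hand_summed_product(self):
        smap = np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9]])
        boundary = np.array(
            [[True, False, True], [False, False, False], [True, True, False]]
        )
        assert contour_saliency_score(smap, boundary) == pytest.approx(
            0.1 + 0.3 + 0.7 + 0.8
        )

    def test_central_scores_exceed_peripheral_on_phantom(self, small_phantom):
        """High-contrast central cross-sections put the true boundary on
        more salient structure than faint peripheral ones."""
        _, stack, gt = small_phantom
        from delinmetrics.synthetic import _true_contour

        cfg = SaliencyConfig(map_resolution=16, output_resolution=128)

        def true_boundary_score(k):
            smap = compute_saliency(stack.images["T1"][k], stack.brain_masks[k], cfg)
            contour = _true_contour(gt.masks[k])
            d = Delineation("gt", "p", k, contour)
            boundary = rasterize_boundary(d, 128, 128)
            return contour_saliency_score(smap, boundary)

        central = np.mean([true_boundary_score(k) for k in (6, 7, 8)])
        peripheral = np.mean([true_boundary_score(k) for k in (3, 4, 11)])
        assert central > peripheral
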