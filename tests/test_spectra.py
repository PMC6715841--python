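"""Hyperspectrum extraction, background handling, Laplacian features."""

import numpy as np
import pytest

import crif
from crif.segmentation import LabelMap
from crif.spectra import LAPLACIAN_KERNEL, estimate_background, laplacian_filter


def _random_spectral(shape_spatial, seed, cfg):
    rng = np.random.default_rng(seed)
    return crif.SpectralStack(rng.uniform(0, 50, size=(6, 32) + shape_spatial), cfg)


class TestExtractHyperspectra:
    def test_constant_stack_gives_constant_spectrum(self, cfg):
        labels = np.zeros((1, 10, 10), dtype=int)
        labels[0, 2:5, 2:5] = 1
        stack = crif.SpectralStack(np.full((6, 32, 1, 10, 10), 7.5), cfg)
        cat = crif.extract_hyperspectra(LabelMap(labels[0]), stack)
        assert len(cat) == 1
        assert np.allclose(cat.entries[0].matrix, 7.5)

    def test_linearity_under_stack_scaling(self, cfg):
        labels = np.zeros((8, 8), dtype=int)
        labels[1:4, 1:4] = 1
        stack = _random_spectral((1, 8, 8), 1, cfg)
        doubled = crif.SpectralStack(stack.intensities * 2, cfg)
        a = crif.extract_hyperspectra(LabelMap(labels), stack)
        b = crif.extract_hyperspectra(LabelMap(labels), doubled)
        assert np.allclose(b.entries[0].matrix, 2 * a.entries[0].matrix)

    def test_matches_masked_mean_loop(self, cfg):
        rng = np.random.default_rng(2)
        labels = np.zeros((12, 12), dtype=int)
        labels[1:4, 1:4] = 1
        labels[6:9, 2:5] = 2
        labels[8:11, 8:11] = 3
        stack = _random_spectral((3, 12, 12), 3, cfg)
        cat = crif.extract_hyperspectra(LabelMap(labels), stack)
        planes = stack.intensities.mean(axis=2)  # 2D mode: z-mean first
        for entry in cat.entries:
            ys, xs = np.nonzero(labels == entry.cell_id)
            for r in range(6):
                for c in range(32):
                    expected = np.mean([planes[r, c, y, x] for y, x in zip(ys, xs)])
                    rel = abs(entry.matrix[r, c] - expected) / abs(expected)
                    assert rel <= 1e-9

    def test_mask_additivity(self, cfg):
        # area-weighted average of two half-masks equals the whole-mask spectrum
        labels_whole = np.zeros((10, 10), dtype=int)
        labels_whole[2:8, 2:8] = 1
        labels_split = np.zeros((10, 10), dtype=int)
        labels_split[2:8, 2:5] = 1
        labels_split[2:8, 5:8] = 2
        stack = _random_spectral((1, 10, 10), 4, cfg)
        whole = crif.extract_hyperspectra(LabelMap(labels_whole), stack).entries[0].matrix
        parts = crif.extract_hyperspectra(LabelMap(labels_split), stack)
        n1 = (labels_split == 1).sum()
        n2 = (labels_split == 2).sum()
        recombined = (n1 * parts.entries[0].matrix + n2 * parts.entries[1].matrix) / (n1 + n2)
        assert np.allclose(whole, recombined, rtol=1e-12)

    def test_empty_map_gives_empty_catalog(self, cfg):
        stack = _random_spectral((1, 6, 6), 5, cfg)
        assert len(crif.extract_hyperspectra(LabelMap(np.zeros((6, 6), dtype=int)), stack)) == 0

    def test_geometry_mismatch_rejected(self, cfg):
        stack = _random_spectral((1, 6, 6), 6, cfg)
        with pytest.raises(ValueError, match="match"):
            crif.extract_hyperspectra(LabelMap(np.zeros((9, 9), dtype=int)), stack)


class TestEstimateBackground:
    def test_cell_free_constant_scene(self, cfg):
        stack = crif.SpectralStack(np.full((6, 32, 1, 8, 8), 3.25), cfg)
        bg = estimate_background(LabelMap(np.zeros((8, 8), dtype=int)), stack)
        assert np.allclose(bg.matrix, 3.25)
        assert bg.n_pixels == 64

    def test_half_field_of_cells_still_exact(self, cfg):
        labels = np.zeros((8, 8), dtype=int)
        labels[:, :4] = 1
        arr = np.full((6, 32, 1, 8, 8), 2.0)
        arr[:, :, :, :, :4] = 99.0  # cell side is bright; background is 2.0
        bg = estimate_background(LabelMap(labels), crif.SpectralStack(arr, cfg), exclusion_radius_px=0)
        assert np.allclose(bg.matrix, 2.0)

    def test_matches_complement_mean_loop(self, cfg, noisy_monolayer):
        truth, _, spectral, labels = noisy_monolayer
        bg = estimate_background(labels, spectral, exclusion_radius_px=2)
        from scipy import ndimage

        cell = ndimage.binary_dilation(
            labels.labels > 0, iterations=2,
            structure=ndimage.generate_binary_structure(2, 2),
        )
        planes = spectral.intensities.mean(axis=2)
        ys, xs = np.nonzero(~cell)
        expected = np.zeros((6, 32))
        for r in range(6):
            for c in range(32):
                expected[r, c] = np.mean([planes[r, c, y, x] for y, x in zip(ys, xs)])
        assert np.allclose(bg.matrix, expected, rtol=1e-9)

    def test_no_background_left_rejected(self, cfg):
        labels = np.ones((6, 6), dtype=int)
        stack = crif.SpectralStack(np.ones((6, 32, 1, 6, 6)), cfg)
        with pytest.raises(ValueError, match="background"):
            estimate_background(LabelMap(labels), stack, exclusion_radius_px=0)


class TestSubtractBackground:
    def _one_cell_catalog(self, cfg, matrix):
        return crif.HyperspectrumCatalog([crif.Hyperspectrum(1, matrix, (0, 0))], None, cfg)

    def test_zero_background_is_identity(self, cfg):
        m = np.arange(192, dtype=float).reshape(6, 32)
        out = crif.subtract_background(self._one_cell_catalog(cfg, m), np.zeros((6, 32)))
        assert np.array_equal(out.entries[0].matrix, m)

    def test_equal_background_gives_zero(self, cfg):
        m = np.full((6, 32), 4.0)
        out = crif.subtract_background(self._one_cell_catalog(cfg, m), m)
        assert np.all(out.entries[0].matrix == 0)

    def test_oversubtraction_clipped_at_zero(self, cfg):
        out = crif.subtract_background(
            self._one_cell_catalog(cfg, np.full((6, 32), 1.0)), np.full((6, 32), 1.5)
        )
        assert np.all(out.entries[0].matrix == 0.0)

    def test_double_subtraction_rejected(self, cfg):
        cat = self._one_cell_catalog(cfg, np.ones((6, 32)))
        once = crif.subtract_background(cat, np.zeros((6, 32)))
        with pytest.raises(ValueError, match="already"):
            crif.subtract_background(once, np.zeros((6, 32)))


class TestLaplacianFilter:
    def test_annihilates_constants(self):
        assert np.allclose(laplacian_filter(np.full((6, 32), 3.7)), 0.0)
        assert np.allclose(laplacian_filter(np.zeros((6, 32))), 0.0)

    def test_impulse_matches_sliding_window_loop(self):
        m = np.zeros((6, 32))
        m[2, 10] = 1.0
        out = laplacian_filter(m)
        padded = np.pad(m, 1, mode="edge")
        expected = np.zeros((6, 32))
        for y in range(6):
            for x in range(32):
                window = padded[y:y + 3, x:x + 3]
                expected[y, x] = (window * LAPLACIAN_KERNEL[::-1, ::-1]).sum()
        assert np.allclose(out, expected)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(6, 32)), rng.normal(size=(6, 32))
        assert np.allclose(
            laplacian_filter(2 * a + 3 * b),
            2 * laplacian_filter(a) + 3 * laplacian_filter(b),
        )

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            laplacian_filter(np.zeros((5, 32)))


class TestFeatureVector:
    def test_length_is_192(self, cfg, signatures):
        fv = crif.to_feature_vector(signatures["pseudomonas_like"].matrix)
        assert fv.values.shape == (192,)

    def test_flattening_convention(self):
        m = np.zeros((6, 32))
        m[1, 0] = 1.0
        fv = crif.to_feature_vector(m, "raw", "none")
        assert fv.values[32] == 1.0 and fv.values.sum() == 1.0

    def test_max1_normalization(self):
        m = np.zeros((6, 32))
        m[0, 0] = 4.0
        m[3, 7] = 2.0
        fv = crif.to_feature_vector(m, "raw", "max1")
        assert fv.values.max() == 1.0
        assert fv.values[3 * 32 + 7] == 0.5

    def test_all_zero_normalization_rejected(self):
        with pytest.raises(ValueError):
            crif.to_feature_vector(np.zeros((6, 32)), "raw", "max1")
        with pytest.raises(ValueError):
            crif.to_feature_vector(np.zeros((6, 32)), "raw", "sum1")


class TestEndToEndRecovery:
    def test_clean_scene_recovers_signature_exactly(self, clean_monolayer, cfg, signatures):
        truth, _, spectral, labels = clean_monolayer
        cat = crif.extract_hyperspectra(labels, spectral)
        cat = crif.subtract_background(cat, truth.background_spectrum(cfg))
        expected = signatures["pseudomonas_like"].matrix
        for entry in cat.entries:
            rel = np.abs(entry.matrix - expected) / np.maximum(expected, 1e-12)
            assert rel[expected > 1e-9].max() <= 1e-6
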