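import numpy as np
import pytest

from netquant.errors import NotBimodalError, ParameterError, ValidationError
from netquant.segmentation import (
    combine_masks,
    intermodes_threshold,
    label_components,
    phansalkar_threshold,
)

from oracles import flood_fill_count, naive_intermodes, naive_phansalkar


class TestIntermodes:
    def test_two_spike_histogram_threshold_is_midpoint(self):
        img = np.array([10] * 500 + [200] * 500, dtype=np.uint8).reshape(20, 50)
        assert intermodes_threshold(img) == pytest.approx(105.0)

    def test_gaussian_mixture_threshold_between_modes(self, rng):
        values = np.concatenate([
            rng.normal(30, 10, 10_000), rng.normal(180, 10, 10_000)])
        img = np.clip(values, 0, 255).astype(np.uint8).reshape(200, 100)
        thr = intermodes_threshold(img)
        assert 90 <= thr <= 120

    def test_matches_exhaustive_smoothing_oracle(self, rng):
        values = np.concatenate([
            rng.normal(40, 12, 5000), rng.normal(200, 15, 3000)])
        img = np.clip(values, 0, 255).astype(np.uint8).reshape(80, 100)
        thr = intermodes_threshold(img)
        hist = np.bincount(img.ravel(), minlength=256).astype(float)
        expected, _ = naive_intermodes(hist, list(range(256)))
        assert thr == pytest.approx(expected)

    def test_constant_image_raises_not_bimodal(self):
        img = np.full((40, 40), 7, dtype=np.uint8)
        with pytest.raises(NotBimodalError) as exc:
            intermodes_threshold(img)
        assert exc.value.iterations == 0

    def test_shift_covariance_on_two_spike_histograms(self):
        base = np.array([20] * 800 + [180] * 200, dtype=np.int64).reshape(25, 40)
        t0 = intermodes_threshold(base.astype(np.uint8))
        t1 = intermodes_threshold((base + 30).astype(np.uint8))
        assert t1 - t0 == pytest.approx(30.0)


class TestPhansalkar:
    def test_all_zero_image_is_all_background(self):
        mask = phansalkar_threshold(np.zeros((40, 40), dtype=np.uint8), radius=5)
        assert not mask.any()

    def test_constant_half_scale_is_all_foreground(self):
        # t = 0.5*(1 + 2*exp(-5) - 0.25) ~ 0.38174 < 0.5
        img = np.full((40, 40), 0.5)
        assert phansalkar_threshold(img, radius=5).all()

    def test_two_plateau_image_splits_at_formula_values(self):
        # left plateau 0.2: t ~ 0.20413 > 0.2 -> background
        # right plateau 0.8: t ~ 0.60054 < 0.8 -> foreground
        img = np.concatenate([np.full((40, 20), 0.2), np.full((40, 20), 0.8)],
                             axis=1)
        mask = phansalkar_threshold(img, radius=5)
        assert not mask[:, :14].any()
        assert mask[:, 26:].all()

    @pytest.mark.parametrize("radius", [1, 3, 7, 15])
    def test_matches_naive_per_pixel_oracle(self, rng, radius):
        img = rng.integers(0, 256, size=(48, 48)).astype(np.uint8)
        fast = phansalkar_threshold(img, radius=radius)
        slow = naive_phansalkar(img, radius=radius, max_value=255)
        assert np.array_equal(fast, slow)

    def test_sixteen_bit_normalisation(self, rng):
        img = rng.integers(0, 65536, size=(40, 40)).astype(np.uint16)
        fast = phansalkar_threshold(img, radius=6)
        slow = naive_phansalkar(img, radius=6, max_value=65535)
        assert np.array_equal(fast, slow)

    def test_oversized_radius_rejected(self):
        with pytest.raises(ParameterError):
            phansalkar_threshold(np.zeros((40, 40), dtype=np.uint8), radius=25)


class TestCombineMasks:
    @staticmethod
    def _fixture():
        glob = np.zeros((20, 20), dtype=bool)
        local = np.zeros((20, 20), dtype=bool)
        local[2:6, 2:6] = True      # fully inside global
        glob[1:8, 1:8] = True
        local[12:16, 12:16] = True  # zero overlap
        return glob, local

    def test_component_inside_global_retained_in_both_modes(self):
        glob, local = self._fixture()
        for mode in ("intersection", "local_seeded_by_global"):
            out = combine_masks(glob, local, mode=mode)
            assert out[2:6, 2:6].all()

    def test_component_without_overlap_removed_in_both_modes(self):
        glob, local = self._fixture()
        for mode in ("intersection", "local_seeded_by_global"):
            out = combine_masks(glob, local, mode=mode)
            assert not out[12:16, 12:16].any()

    def test_single_pixel_overlap_kept_whole_vs_clipped(self):
        glob = np.zeros((10, 10), dtype=bool)
        local = np.zeros((10, 10), dtype=bool)
        local[4, 2:8] = True
        glob[4, 2] = True  # one-pixel seed
        seeded = combine_masks(glob, local, mode="local_seeded_by_global")
        inter = combine_masks(glob, local, mode="intersection")
        assert seeded.sum() == 6  # whole component survives
        assert inter.sum() == 1   # clipped to the overlap
        # brute-force check of the seeded result
        comps = flood_fill_count(local)
        expected = set().union(*(c for c in comps if any(glob[i, j] for i, j in c)))
        assert {tuple(p) for p in np.argwhere(seeded)} == expected

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            combine_masks(np.zeros((5, 5), bool), np.zeros((6, 6), bool))


class TestLabelComponents:
    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3, 3] = mask[4, 4] = True
        assert label_components(mask, connectivity=8, min_area_px=1).n_labels == 1
        assert label_components(mask, connectivity=4, min_area_px=1).n_labels == 2
        # both dropped under the default speckle floor
        assert label_components(mask, connectivity=4, min_area_px=10).n_labels == 0

    def test_square_is_one_label(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        lm = label_components(mask)
        assert lm.n_labels == 1
        assert (lm.labels > 0).sum() == 100

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_brute_force_flood_fill(self, rng, connectivity):
        mask = rng.random((60, 60)) < 0.35
        lm = label_components(mask, connectivity=connectivity, min_area_px=1)
        comps = flood_fill_count(mask, connectivity=connectivity)
        assert lm.n_labels == len(comps)
        # the set of component pixel-sets is identical (scan-order invariant)
        got = {frozenset(map(tuple, np.argwhere(lm.labels == i)))
               for i in range(1, lm.n_labels + 1)}
        assert got == set(comps)

    def test_labels_contiguous_after_speckle_removal(self, rng):
        mask = rng.random((50, 50)) < 0.3
        lm = label_components(mask, min_area_px=5)
        present = np.unique(lm.labels)
        assert present[0] == 0 or lm.n_labels == 0
        assert list(present[present > 0]) == list(range(1, lm.n_labels + 1))
        areas = np.bincount(lm.labels.ravel())[1:]
        assert (areas >= 5).all()
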