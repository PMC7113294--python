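import numpy as np
import pytest
from skimage.feature import graycomatrix

from conftest import make_slab
from octbiofilm.preprocess import max_intensity_projection, three_class_label
from octbiofilm.structure import (
    global_porosity,
    height_map,
    intrinsic_porosity,
    local_thickness,
    mean_biofilm_thickness,
    substratum_coverage,
    textural_entropy,
)
from oracles import (
    brute_global_porosity,
    brute_intrinsic_porosity,
    brute_mean_thickness,
    brute_substratum_coverage,
    brute_textural_entropy,
    random_binary_volume,
)


class TestLocalThickness:
    def test_full_column(self):
        col = np.full(10, 255, dtype=np.uint8)
        assert local_thickness(col, 2.1) == pytest.approx(21.0)

    def test_empty_column(self):
        assert local_thickness(np.zeros(10, dtype=np.uint8), 2.1) == 0.0

    def test_voids_do_not_add_thickness_in_sum_mode(self):
        col = np.array([255, 0, 255], dtype=np.uint8)
        assert local_thickness(col, 1.0) == pytest.approx(2.0)
        # the interface alternative counts up to the topmost biomass voxel
        assert local_thickness(col, 1.0, mode="interface") == pytest.approx(3.0)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            local_thickness(np.array([1, 2, 3], dtype=np.uint8), 1.0)


class TestMeanThickness:
    def test_uniform_slab(self):
        vol = make_slab(12, 5, 5, k=7)
        assert mean_biofilm_thickness(vol, 2.1) == pytest.approx(7 * 2.1)

    def test_half_covered(self):
        vol = np.zeros((15, 2, 4), dtype=np.uint8)
        vol[:10, :, :2] = 255  # half the columns carry a 10-voxel slab
        assert mean_biofilm_thickness(vol, 1.0) == pytest.approx(5.0)

    def test_equals_global_sum_formula(self, rng):
        vol = random_binary_volume(rng)
        n_cols = vol.shape[1] * vol.shape[2]
        expected = vol.sum(dtype=np.int64) / 255 * 1.7 / n_cols
        assert mean_biofilm_thickness(vol, 1.7) == pytest.approx(expected)

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError):
            mean_biofilm_thickness(np.zeros((0, 2, 2), np.uint8), 1.0)


class TestSubstratumCoverage:
    def test_empty_channel_is_zero(self):
        assert substratum_coverage(np.zeros((50, 50), dtype=np.uint8)) == 0.0

    def test_full_coverage(self):
        assert substratum_coverage(np.full((10, 10), 255, np.uint8)) == 100.0

    def test_exact_half(self):
        mip = np.zeros((10, 10), dtype=np.uint8)
        mip[:5] = 200
        assert substratum_coverage(mip) == pytest.approx(50.0)

    def test_any_nonzero_value_counts_as_biomass(self):
        mip = np.zeros((4, 4), dtype=np.uint8)
        mip[0, 0] = 1
        assert substratum_coverage(mip) == pytest.approx(100 / 16)


class TestPorosities:
    def test_solid_slab_zero_porosity(self):
        labels = three_class_label(make_slab(8, 4, 4, k=5))
        assert intrinsic_porosity(labels) == 0.0
        assert global_porosity(labels) == 0.0

    def test_equal_voids_and_biomass(self):
        # construct directly: half the labeled voxels void, half biomass
        labels = np.zeros((4, 2, 2), dtype=np.uint8)
        labels[0] = 150
        labels[1] = 50
        assert intrinsic_porosity(labels) == pytest.approx(50.0)

    def test_one_void_per_ten_voxel_column(self):
        vol = make_slab(12, 3, 3, k=10)
        vol[4] = 0  # one internal void voxel per column of height 10
        labels = three_class_label(vol)
        assert global_porosity(labels) == pytest.approx(10.0)
        assert intrinsic_porosity(labels) == pytest.approx(10.0)

    def test_background_slices_above_do_not_matter(self, rng):
        vol = random_binary_volume(rng, max_side=10)
        labels = three_class_label(vol)
        padded = three_class_label(
            np.concatenate([vol, np.zeros((6,) + vol.shape[1:], np.uint8)])
        )
        assert intrinsic_porosity(padded) == intrinsic_porosity(labels)

    def test_empty_volume_is_missing(self):
        labels = np.zeros((4, 3, 3), dtype=np.uint8)
        assert np.isnan(intrinsic_porosity(labels))
        assert np.isnan(global_porosity(labels))


class TestHeightMap:
    def test_uniform_slab(self):
        hm = height_map(make_slab(10, 3, 3, k=4), 2.0)
        np.testing.assert_allclose(hm.heights, 8.0)

    def test_single_voxel_column(self):
        vol = np.zeros((12, 2, 2), dtype=np.uint8)
        vol[9, 1, 0] = 255
        hm = height_map(vol, 2.0)
        assert hm.heights[1, 0] == pytest.approx(20.0)
        assert hm.heights[0, 0] == 0.0

    def test_bounded_by_channel_height(self, rng):
        vol = random_binary_volume(rng)
        hm = height_map(vol, 2.1)
        assert hm.heights.max() <= vol.shape[0] * 2.1 + 1e-9
        assert (hm.heights >= 0).all()

    def test_mean_height_bounds_mean_thickness(self, rng):
        """With voids, per-column thickness ≤ interface height; means follow."""
        vol = random_binary_volume(rng)
        thickness = mean_biofilm_thickness(vol, 2.1)
        assert thickness <= height_map(vol, 2.1).mean + 1e-9


class TestTexturalEntropy:
    def test_homogeneous_image_is_zero(self):
        img = np.full((20, 20), 137, dtype=np.uint8)
        assert textural_entropy(img) == 0.0

    def test_two_phase_stripes_ln2(self):
        # alternating width-1 vertical stripes, odd width so the two ordered
        # transitions a→b and b→a occur equally often: p = 1/2 each → ln 2
        img = np.tile(np.array([10, 200], dtype=np.uint8), (8, 9))[:, :17]
        assert textural_entropy(img, (0, 1)) == pytest.approx(np.log(2))

    def test_matches_brute_force_pair_loop(self, rng):
        for offset in [(0, 1), (1, 0), (1, 1), (1, -1), (0, 2)]:
            img = rng.integers(0, 8, size=(12, 14), dtype=np.uint8) * 30
            assert textural_entropy(img, offset) == pytest.approx(
                brute_textural_entropy(img, offset)
            )

    def test_matches_skimage_cooccurrence(self, rng):
        """Cross-check the co-occurrence table against skimage's GLCM."""
        img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
        glcm = graycomatrix(img, [1], [0], levels=256, symmetric=False, normed=True)
        p = glcm[:, :, 0, 0]
        expected = -(p[p > 0] * np.log(p[p > 0])).sum()
        assert textural_entropy(img, (0, 1)) == pytest.approx(expected)

    def test_intensity_relabeling_invariance(self, rng):
        img = rng.integers(0, 16, size=(10, 10), dtype=np.uint8)
        perm = rng.permutation(256).astype(np.uint8)
        assert textural_entropy(perm[img]) == pytest.approx(textural_entropy(img))

    def test_offset_reversal_and_symmetrization(self, rng):
        img = rng.integers(0, 6, size=(9, 11), dtype=np.uint8) * 40
        # transpose relation: reversing the offset transposes the table,
        # which leaves the entropy of the distribution unchanged
        assert textural_entropy(img, (0, 1)) == pytest.approx(
            textural_entropy(img, (0, -1))
        )
        assert textural_entropy(img, (1, 1), symmetric=True) == pytest.approx(
            textural_entropy(img, (-1, -1), symmetric=True)
        )

    def test_image_smaller_than_offset_rejected(self):
        with pytest.raises(ValueError):
            textural_entropy(np.zeros((2, 2), dtype=np.uint8), (0, 5))


class TestAxisSwapInvariance:
    def test_parameters_invariant_under_xy_swap(self, rng):
        vol = random_binary_volume(rng)
        swapped = np.swapaxes(vol, 1, 2)
        assert mean_biofilm_thickness(vol, 2.1) == pytest.approx(
            mean_biofilm_thickness(swapped, 2.1)
        )
        assert substratum_coverage(max_intensity_projection(vol)) == pytest.approx(
            substratum_coverage(max_intensity_projection(swapped))
        )
        la, lb = three_class_label(vol), three_class_label(swapped)
        assert intrinsic_porosity(la) == pytest.approx(intrinsic_porosity(lb))
        assert global_porosity(la) == pytest.approx(global_porosity(lb))


class TestOracleAgreement:
    def test_all_parameters_match_brute_force(self, rng):
        """Vectorised and loop implementations agree on random volumes."""
        for _ in range(10):
            vol = random_binary_volume(rng, max_side=12)
            labels = three_class_label(vol)
            mip = max_intensity_projection(vol)
            assert substratum_coverage(mip) == pytest.approx(
                brute_substratum_coverage(mip)
            )
            assert mean_biofilm_thickness(vol, 2.1) == pytest.approx(
                brute_mean_thickness(vol, 2.1)
            )
            assert intrinsic_porosity(labels) == pytest.approx(
                brute_intrinsic_porosity(labels), nan_ok=True
            )
            assert global_porosity(labels) == pytest.approx(
                brute_global_porosity(labels), nan_ok=True
            )
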