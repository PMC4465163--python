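"""SUV metrics, discretization, GLCM and NGTDM against hand values and
exhaustive enumeration oracles."""

import numpy as np
import pytest

from pettex import PETVolume, VOIMask, compute_glcm, compute_ngtdm, \
    discretize_suv, extract_all_features, glcm_features, ngtdm_features, \
    suv_statistics
from pettex.features import EPS_COARSENESS, FeatureError, GLCMatrix, \
    NGTDMTable, OFFSETS_13

from _oracles import (naive_coarseness_busyness, naive_glcm_contrast,
                      naive_glcm_correlation, naive_glcm_entropy,
                      naive_glcm_merged, naive_ngtdm)
from conftest import random_voi


def line_voi(values, spacing=(1.0, 1.0, 1.0)):
    """A 1 x 1 x n volume fully covered by its VOI."""
    arr = np.asarray(values, dtype=float)[None, None, :]
    vol = PETVolume(arr, spacing)
    mask = VOIMask(np.ones_like(arr, bool), threshold_suv=0.1,
                   connectivity=26, seed_voxel=(0, 0, 0))
    return vol, mask


class TestSUVStatistics:
    def test_hand_values(self):
        vol, mask = line_voi([2.0, 4.0, 6.0], spacing=(4.06, 4.06, 5.0))
        s = suv_statistics(vol, mask)
        assert s.suv_max == 6.0
        assert s.suv_mean == 4.0
        assert s.mtv_ml == pytest.approx(3 * 4.06 * 4.06 * 5.0 / 1000.0)
        # population SD of {2,4,6} is sqrt(8/3)
        assert s.cov == pytest.approx(np.sqrt(8.0 / 3.0) / 4.0)

    def test_constant_region_cov_zero(self):
        vol, mask = line_voi([3.0, 3.0, 3.0, 3.0])
        assert suv_statistics(vol, mask).cov == 0.0

    def test_single_voxel(self):
        vol, mask = line_voi([5.0])
        s = suv_statistics(vol, mask)
        assert s.suv_max == s.suv_mean == 5.0
        assert s.cov == 0.0
        assert s.mtv_ml == pytest.approx(1e-3)

    def test_shape_mismatch_rejected(self):
        vol, _ = line_voi([1.0, 2.0])
        bad = VOIMask(np.ones((1, 1, 3), bool), 0.1, 26, (0, 0, 0))
        with pytest.raises(FeatureError):
            suv_statistics(vol, bad)


class TestDiscretization:
    def test_printed_rule_hand_values(self):
        # R = 64 (I - min)/(max - min): {2, 4, 6} -> R {0, 32, 64} -> bins {1, 33, 64}
        vol, mask = line_voi([2.0, 4.0, 6.0])
        d = discretize_suv(vol, mask)
        np.testing.assert_array_equal(d.bins[mask.mask], [1, 33, 64])
        assert (d.suv_min, d.suv_max) == (2.0, 6.0)

    def test_flat_voi_all_bins_one(self):
        vol, mask = line_voi([4.0, 4.0, 4.0])
        np.testing.assert_array_equal(
            discretize_suv(vol, mask).bins[mask.mask], [1, 1, 1])

    def test_bins_always_within_range(self, rng):
        for _ in range(50):
            vals = rng.uniform(0, 30, size=rng.integers(1, 40))
            vol, mask = line_voi(vals)
            b = discretize_suv(vol, mask).bins[mask.mask]
            assert b.min() >= 1 and b.max() <= 64
            if vals.max() > vals.min():
                assert b.max() == 64 and b.min() == 1


class TestGLCM:
    def test_1d_hand_counts(self):
        vol, mask = line_voi([2.0, 2.0, 6.0])  # bins [1, 1, 64]
        d = discretize_suv(vol, mask)
        g = compute_glcm(d, mask)
        occupied = g.p[np.ix_([0, 63], [0, 63])]
        np.testing.assert_allclose(occupied, [[0.5, 0.25], [0.25, 0.0]])

    def test_constant_voi_single_diagonal_cell(self):
        vol, mask = line_voi([4.0, 4.0, 4.0])
        g = compute_glcm(discretize_suv(vol, mask), mask)
        assert g.p[0, 0] == 1.0 and g.p.sum() == 1.0

    def test_symmetric_and_normalized(self, textured_phantom):
        from pettex import segment_isocontour
        mask = segment_isocontour(textured_phantom, 2.0)
        g = compute_glcm(discretize_suv(textured_phantom, mask), mask)
        assert abs(g.p.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(g.p, g.p.T, atol=0)

    def test_no_neighbors_rejected(self):
        bins = np.zeros((3, 3, 3), dtype=np.int64)
        bins[0, 0, 0] = bins[2, 2, 2] = 1
        mask_arr = bins > 0
        mask_arr[1, 1, 1] = False  # two isolated corner voxels
        from pettex.features import DiscretizedVolume
        d = DiscretizedVolume(bins, 64, 1.0, 1.0)
        m = VOIMask.__new__(VOIMask)  # bypass single-component validation
        m.mask, m.threshold_suv, m.connectivity, m.seed_voxel = \
            mask_arr, 2.0, 6, (0, 0, 0)
        with pytest.raises(FeatureError, match="no co-occurrences"):
            compute_glcm(d, m, offsets=[(0, 0, 1)])

    def test_features_hand_values(self):
        p = np.zeros((64, 64))
        p[0, 0], p[0, 1], p[1, 0] = 0.5, 0.25, 0.25
        f = glcm_features(GLCMatrix(p, OFFSETS_13, "merged"))
        assert f.entropy == pytest.approx(1.5)       # -(.5 lg .5 + 2 * .25 lg .25)
        assert f.contrast == pytest.approx(0.5)      # off-diagonal mass at |i-j|=1
        assert -1.0 <= f.correlation <= 1.0

    def test_degenerate_single_level(self):
        p = np.zeros((64, 64))
        p[3, 3] = 1.0
        with pytest.warns(RuntimeWarning):
            f = glcm_features(GLCMatrix(p, OFFSETS_13, "merged"))
        assert (f.entropy, f.contrast, f.correlation) == (0.0, 0.0, 1.0)

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(FeatureError):
            glcm_features(GLCMatrix(np.full((4, 4), 0.5), OFFSETS_13, "merged"))

    def test_merged_matches_exhaustive_enumeration(self, rng):
        from pettex.features import DiscretizedVolume
        checked = 0
        for _ in range(40):
            bins, mask_arr = random_voi(rng)
            ref = naive_glcm_merged(bins, mask_arr, 6)
            d = DiscretizedVolume(bins * mask_arr, 6, 0.0, 1.0)
            m = VOIMask.__new__(VOIMask)
            m.mask, m.threshold_suv, m.connectivity, m.seed_voxel = \
                mask_arr, 1.0, 26, tuple(np.argwhere(mask_arr)[0])
            if ref.sum() == 0:
                with pytest.raises(FeatureError):
                    compute_glcm(d, m)
                continue
            g = compute_glcm(d, m)
            np.testing.assert_allclose(g.p, ref, atol=1e-14)
            f = glcm_features(g)
            assert f.entropy == pytest.approx(naive_glcm_entropy(ref))
            assert f.contrast == pytest.approx(naive_glcm_contrast(ref))
            assert f.correlation == pytest.approx(naive_glcm_correlation(ref))
            checked += 1
        assert checked >= 20

    def test_rotation_invariance_of_merged_features(self, textured_phantom):
        """The 13-offset set is closed under 90-degree rotations modulo sign,
        so pooled-count features must not change when the volume rotates."""
        from pettex import segment_isocontour
        v0 = textured_phantom
        f0 = extract_all_features(v0, 2.0)
        rot = PETVolume(np.rot90(v0.suv, k=1, axes=(1, 2)).copy(),
                        v0.spacing_mm)
        f1 = extract_all_features(rot, 2.0)
        for name in ("entropy", "correlation", "contrast", "coarseness",
                     "busyness", "suv_max", "cov"):
            assert getattr(f0, name) == pytest.approx(getattr(f1, name),
                                                      rel=1e-12)


class TestNGTDM:
    def test_1d_hand_enumeration(self):
        vol, mask = line_voi([2.0, 2.031, 2.0])
        d = discretize_suv(vol, mask)          # bins [1, 64, 1] after scaling
        np.testing.assert_array_equal(d.bins[mask.mask], [1, 64, 1])
        t = compute_ngtdm(d, mask)
        # center voxel (level 64): its only neighbors are the two level-1
        # edges -> s_64 = 63; each edge voxel's sole neighbor is the center
        # -> s_1 = 2 * 63
        assert dict(zip(t.levels, t.s)) == pytest.approx({1: 126.0, 64: 63.0})
        assert dict(zip(t.levels, t.p)) == pytest.approx({1: 2 / 3, 64: 1 / 3})

    def test_probabilities_sum_to_one(self, textured_phantom):
        from pettex import segment_isocontour
        mask = segment_isocontour(textured_phantom, 2.0)
        t = compute_ngtdm(discretize_suv(textured_phantom, mask), mask)
        assert t.p.sum() == pytest.approx(1.0)
        assert np.all(t.s >= 0)

    def test_constant_voi(self):
        vol, mask = line_voi([4.0, 4.0, 4.0])
        t = compute_ngtdm(discretize_suv(vol, mask), mask)
        coarseness, busyness = ngtdm_features(t)
        assert coarseness == pytest.approx(1.0 / EPS_COARSENESS)
        assert busyness == 0.0

    def test_two_level_hand_values(self):
        t = NGTDMTable(levels=np.array([1, 2]), p=np.array([0.5, 0.5]),
                       s=np.array([1.0, 1.0]))
        coarseness, busyness = ngtdm_features(t)
        assert coarseness == pytest.approx(1.0 / (EPS_COARSENESS + 1.0))
        assert busyness == pytest.approx(1.0)  # denominator 2 |.5 - 1.| = 1

    def test_matches_exhaustive_enumeration(self, rng):
        from pettex.features import DiscretizedVolume
        for _ in range(40):
            bins, mask_arr = random_voi(rng)
            ref = naive_ngtdm(bins, mask_arr)
            d = DiscretizedVolume(bins * mask_arr, 6, 0.0, 1.0)
            m = VOIMask.__new__(VOIMask)
            m.mask, m.threshold_suv, m.connectivity, m.seed_voxel = \
                mask_arr, 1.0, 26, tuple(np.argwhere(mask_arr)[0])
            if not ref:
                with pytest.raises(FeatureError):
                    compute_ngtdm(d, m)
                continue
            t = compute_ngtdm(d, m)
            got = {int(l): (p, s) for l, p, s in zip(t.levels, t.p, t.s)}
            assert got.keys() == ref.keys()
            for lvl in ref:
                assert got[lvl][0] == pytest.approx(ref[lvl][0])
                assert got[lvl][1] == pytest.approx(ref[lvl][1])
            assert ngtdm_features(t) == pytest.approx(
                naive_coarseness_busyness(ref))


class TestExtractAll:
    def test_flat_tumor_degenerate_suite(self, flat_phantom):
        f = extract_all_features(flat_phantom, 2.0)
        assert f.entropy == 0.0
        assert f.contrast == 0.0
        assert f.cov == 0.0
        assert f.busyness == 0.0
        assert f.coarseness == pytest.approx(1.0 / EPS_COARSENESS)

    def test_suvmax_identical_across_thresholds(self, textured_phantom):
        f20 = extract_all_features(textured_phantom, 2.0)
        f25 = extract_all_features(textured_phantom, 2.5)
        assert f20.suv_max == f25.suv_max

    def test_tiny_volume_full_brute_force(self):
        """Every feature on a crafted 5-cube equals its naive recomputation."""
        rng = np.random.default_rng(7)
        arr = rng.uniform(2.5, 9.0, size=(5, 5, 5))
        arr[0, :, :] = 0.2  # give segmentation something to exclude
        vol = PETVolume(arr, (1.0, 1.0, 1.0))
        f = extract_all_features(vol, 2.0)
        from pettex import segment_isocontour
        mask = segment_isocontour(vol, 2.0)
        d = discretize_suv(vol, mask)
        ref = naive_glcm_merged(d.bins, mask.mask, 64)
        assert f.entropy == pytest.approx(naive_glcm_entropy(ref))
        assert f.contrast == pytest.approx(naive_glcm_contrast(ref))
        assert f.correlation == pytest.approx(naive_glcm_correlation(ref))
        ref_t = naive_ngtdm(d.bins, mask.mask)
        assert (f.coarseness, f.busyness) == pytest.approx(
            naive_coarseness_busyness(ref_t))
        vals = arr[mask.mask]
        assert f.suv_max == vals.max()
        assert f.suv_mean == pytest.approx(vals.mean())
        assert f.cov == pytest.approx(vals.std() / vals.mean())
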