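"""Tests for discretization, matrix builders and feature formulas.

The two worked examples (a constant 2x2 patch; a 1x4 row with bins
[1,1,2,2]) have all 32 features derived by hand from the IBSI formulas and
are asserted to 1e-12 in test_acceptance; here the matrices themselves and
the builder conventions are exercised, including equivalence with
brute-force pair/run enumeration.
"""

import numpy as np
import pytest

import texrobust as tx
from texrobust.errors import DegenerateMatrixError, DomainError
from texrobust.texture import DIRECTIONS_2D, DIRECTIONS_3D

from oracles import glcm_counts_bruteforce, glrlm_counts_bruteforce

X_DIR = [(1, 0, 0)]


def roi_from_bins(bins: np.ndarray, spacing=(1.0, 1.0, 1.0), mask=None):
    """Build (volume, mask) whose default discretization yields ``bins``.

    Bin b maps to the centre HU of bin b: hu = -200 + (b-1)*15 + 7.
    """
    bins = np.asarray(bins)
    hu = np.where(bins > 0, -200.0 + (bins - 1) * 15.0 + 7.0, 110.0)
    vol = tx.IntensityVolume(values=hu.astype(float), spacing=spacing)
    if mask is None:
        mask = bins > 0
    roi = tx.RoiMask(values=mask, spacing=spacing)
    return vol, roi


class TestDiscretize:
    @pytest.mark.parametrize("hu,expected_bin", [
        (-200.0, 1), (279.0, 32),       # window endpoints
        (-186.0, 1), (-185.0, 2),       # 15-HU bin edge
        (-250.0, 1), (500.0, 32),       # clamped below / above
    ])
    def test_bin_mapping(self, hu, expected_bin):
        vol = tx.IntensityVolume(values=np.full((2, 2, 1), hu), spacing=(1, 1, 1))
        mask = tx.RoiMask(values=np.ones((2, 2, 1), dtype=bool), spacing=(1, 1, 1))
        with np.errstate(all="ignore"):
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = tx.discretize(vol, mask)
        assert set(np.unique(d.bin_labels[mask.values])) == {expected_bin}

    def test_clamp_counter(self):
        vals = np.array([[[-250.0], [0.0]], [[500.0], [100.0]]])
        vol = tx.IntensityVolume(values=vals, spacing=(1, 1, 1))
        mask = tx.RoiMask(values=np.ones((2, 2, 1), dtype=bool), spacing=(1, 1, 1))
        d = tx.discretize(vol, mask)
        assert d.n_clamped == 2

    def test_all_outside_window_warns(self):
        vol = tx.IntensityVolume(values=np.full((2, 2, 1), 900.0), spacing=(1, 1, 1))
        mask = tx.RoiMask(values=np.ones((2, 2, 1), dtype=bool), spacing=(1, 1, 1))
        with pytest.warns(UserWarning, match="outside the discretization window"):
            tx.discretize(vol, mask)

    def test_default_window_properties(self):
        cfg = tx.DiscretizationConfig()
        assert cfg.n_grey_levels == 480
        assert cfg.bin_width == 15.0
        with pytest.raises(DomainError):
            tx.DiscretizationConfig(hu_min=-200, hu_max=280)   # 481 levels / 32


class TestBuildGlcm:
    def test_constant_patch_single_entry(self):
        vol, mask = roi_from_bins(np.ones((2, 2, 1), dtype=int))
        m = tx.build_glcm(tx.discretize(vol, mask), mode="2D")
        assert m.glcm[0, 0] == 1.0 and m.glcm.sum() == 1.0

    def test_row_1122_single_direction(self):
        vol, mask = roi_from_bins(np.array([1, 1, 2, 2]).reshape(4, 1, 1))
        d = tx.discretize(vol, mask)
        m = tx.build_glcm(d, mode="2D", directions=X_DIR)
        p = m.glcm
        assert p[0, 0] == pytest.approx(1 / 3)
        assert p[1, 1] == pytest.approx(1 / 3)
        assert p[0, 1] == pytest.approx(1 / 6)
        assert p[1, 0] == pytest.approx(1 / 6)

    def test_symmetry_and_normalisation(self, small_lesion):
        _, vol, truth = small_lesion
        m = tx.build_glcm(tx.discretize(vol, truth), mode="3D")
        assert np.allclose(m.glcm, m.glcm.T)
        assert m.glcm.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_voxel_degenerate(self):
        bins = np.zeros((3, 3, 1), dtype=int)
        bins[1, 1, 0] = 1
        vol, mask = roi_from_bins(bins)
        with pytest.raises(DegenerateMatrixError):
            tx.build_glcm(tx.discretize(vol, mask), mode="2D")

    @pytest.mark.parametrize("mode,dirs", [("3D", DIRECTIONS_3D),
                                           ("2D", DIRECTIONS_2D)])
    def test_direction_sets(self, mode, dirs):
        assert len(DIRECTIONS_3D) == 13 and len(DIRECTIONS_2D) == 4
        vol, mask = roi_from_bins(np.ones((3, 3, 3), dtype=int))
        m = tx.build_glcm(tx.discretize(vol, mask), mode=mode)
        assert m.directions_used == dirs


class TestBuildGlrlm:
    def test_constant_row_single_run(self):
        vol, mask = roi_from_bins(np.ones((4, 1, 1), dtype=int))
        m = tx.build_glrlm(tx.discretize(vol, mask), mode="2D", directions=X_DIR)
        assert m.glrlm[0, 3] == 1 and m.glrlm.sum() == 1

    def test_row_1121_run_decomposition(self):
        vol, mask = roi_from_bins(np.array([1, 1, 2, 1]).reshape(4, 1, 1))
        m = tx.build_glrlm(tx.discretize(vol, mask), mode="2D", directions=X_DIR)
        r = m.glrlm
        assert r[0, 0] == 1 and r[0, 1] == 1 and r[1, 0] == 1 and r.sum() == 3

    def test_mask_hole_truncates_run(self):
        bins = np.ones((5, 1, 1), dtype=int)
        mask = np.ones((5, 1, 1), dtype=bool)
        mask[2] = False
        vol, roi = roi_from_bins(bins, mask=mask)
        m = tx.build_glrlm(tx.discretize(vol, roi), mode="2D", directions=X_DIR)
        assert m.glrlm[0, 1] == 2 and m.glrlm.sum() == 2

    def test_run_conservation(self, small_lesion):
        """Sum_j j * r(i, j) over the direction-summed matrix equals
        n_directions * n_foreground."""
        _, vol, truth = small_lesion
        d = tx.discretize(vol, truth)
        for mode, ndir in (("3D", 13), ("2D", 4)):
            m = tx.build_glrlm(d, mode=mode)
            j = np.arange(1, m.glrlm.shape[1] + 1)
            assert (m.glrlm * j).sum() == ndir * d.n_foreground


@pytest.mark.parametrize("seed", range(10))
def test_matrix_builders_match_bruteforce(seed):
    """Vectorised GLCM/GLRLM equal naive enumeration on random small ROIs."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(2, 7, size=3))
    bins = rng.integers(1, 5, size=shape)
    mask = rng.random(shape) < 0.7
    bins = np.where(mask, bins, 0)
    if not (bins > 0).any():
        bins[0, 0, 0] = 1
    vol, roi = roi_from_bins(bins, mask=bins > 0)
    d = tx.discretize(vol, roi)
    for mode, dirs in (("3D", DIRECTIONS_3D), ("2D", DIRECTIONS_2D)):
        oracle_r = glrlm_counts_bruteforce(d.bin_labels, dirs, 32)
        m_r = tx.build_glrlm(d, mode=mode)
        assert np.array_equal(m_r.glrlm, oracle_r)
        oracle_c = glcm_counts_bruteforce(d.bin_labels, dirs, True, 32)
        total = oracle_c.sum()
        if total == 0:
            continue
        m_c = tx.build_glcm(d, mode=mode)
        assert np.array_equal(m_c.glcm, oracle_c / total)


class TestFeatureProperties:
    def test_constant_image_degenerate_features(self):
        vol, mask = roi_from_bins(np.full((3, 3, 1), 5, dtype=int))
        m = tx.build_glcm(tx.discretize(vol, mask), mode="2D")
        f = tx.glcm_features(m)
        assert f["Energy"] == 1.0 and f["Entropy"] == 0.0
        assert f["Contrast"] == 0.0 and f["MaxProbability"] == 1.0
        assert f["Dissimilarity"] == 0.0 and f["Homogeneity"] == 1.0
        for name in ("Correlation", "InformationMeasureCorrel1",
                     "InformationMeasureCorrel2", "InverseVariance"):
            assert np.isnan(f[name])

    def test_morphology_cube(self):
        mask = tx.RoiMask(values=np.ones((10, 10, 10), dtype=bool),
                          spacing=(1, 1, 1))
        f = tx.morphology_features(mask)
        assert f["NumberOfVoxels"] == 1000
        assert f["Volume"] == pytest.approx(1.0)
        assert f["Max3DDiameter"] == pytest.approx(9 * np.sqrt(3))

    def test_morphology_single_voxel_and_pair(self):
        vals = np.zeros((4, 4, 7), dtype=bool)
        vals[1, 1, 1] = True
        f = tx.morphology_features(tx.RoiMask(values=vals, spacing=(1, 1, 1)))
        assert f == {"Max3DDiameter": 0.0, "NumberOfVoxels": 1.0,
                     "Volume": 0.001}
        vals[1, 1, 4] = True     # 3 slices apart at 3 mm z-spacing
        f = tx.morphology_features(tx.RoiMask(values=vals, spacing=(1, 1, 3)))
        assert f["Max3DDiameter"] == pytest.approx(9.0)

    def test_extract_features_roster_and_determinism(self, small_lesion):
        _, vol, truth = small_lesion
        fv1 = tx.extract_features(vol, truth, mode="3D")
        fv2 = tx.extract_features(vol, truth, mode="3D")
        assert fv1.features == fv2.features
        assert len(fv1.texture()) == 32
        assert set(fv1.texture()) == set(tx.TEXTURE_FEATURES)
        assert 0 < fv1["Energy"] <= 1 and 0 < fv1["MaxProbability"] <= 1
        assert fv1["Entropy"] >= 0
        assert 0 < fv1["RunPercentage"] <= 1 and 0 < fv1["SRE"] <= 1

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        hu = rng.uniform(-100, 200, size=(14, 14, 6))
        big = np.tile(hu, (2, 1, 1))          # identical texture copy
        vol = tx.IntensityVolume(values=big, spacing=(0.8, 0.8, 3.0))
        mask_vals = np.zeros_like(big, dtype=bool)
        mask_vals[3:10, 3:10, 1:5] = True
        shifted = np.roll(mask_vals, 14, axis=0)
        m1 = tx.RoiMask(values=mask_vals, spacing=(0.8, 0.8, 3.0))
        m2 = tx.RoiMask(values=shifted, spacing=(0.8, 0.8, 3.0))
        f1 = tx.extract_features(vol, m1, mode="3D")
        f2 = tx.extract_features(vol, m2, mode="3D")
        for name in tx.TEXTURE_FEATURES:
            assert f1[name] == pytest.approx(f2[name], abs=1e-12)

    def test_single_slice_glcm_same_in_2d_and_3d_modes(self, small_lesion):
        """Out-of-plane pairs vanish on a single-slice mask, so the 3D-mode
        GLCM equals the 2D-mode GLCM."""
        _, vol, truth = small_lesion
        cs = tx.largest_axial_cross_section(truth)
        d = tx.discretize(vol, cs)
        g2 = tx.build_glcm(d, mode="2D")
        g3 = tx.build_glcm(d, mode="3D")
        assert np.allclose(g2.glcm, g3.glcm, atol=1e-15)
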