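"""Radiomic features: discretization, first order, texture families,
assembly, and agreement with the loop-based oracle."""

import numpy as np
import pandas as pd
import pytest

from robustrad.core import ALL_MAP_NAMES, Mask3D, ParametricMap
from robustrad.features import (
    DegenerateROIError,
    FEATURE_NAMES,
    N_FEATURES_PER_MAP,
    discretize,
    extract_feature_table,
    extract_feature_vector,
    first_order_features,
    texture_features,
)
from robustrad.features.extract import extract_features_for_maps
from robustrad.config import DEFAULT_BIN_WIDTHS

from naive_ibsi import naive_feature_vector

ONES = (1.0, 1.0, 1.0)


def _droi(values, mask=None, bw=1.0):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    return discretize(values, mask, bw)


class TestDiscretize:
    def test_floor_rule(self):
        vals = np.array([0.0, 24.9, 25.0, 50.0]).reshape(4, 1, 1)
        d = _droi(vals, bw=25.0)
        assert d.levels[:, 0, 0].tolist() == [1, 1, 2, 3]

    def test_constant_roi_single_level(self):
        d = _droi(np.full((3, 3, 1), 7.0))
        assert d.n_levels == 1

    def test_bin_width_above_range_gives_one_level(self):
        d = _droi(np.arange(8.0).reshape(2, 2, 2), bw=100.0)
        assert np.all(d.levels[d.mask] == 1)

    def test_all_nan_roi_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            _droi(np.full((2, 2, 2), np.nan))

    def test_nan_voxels_dropped_from_effective_mask(self):
        vals = np.array([[1.0, np.nan], [2.0, 3.0]]).reshape(2, 2, 1)
        d = _droi(vals)
        assert d.n_voxels == 3


class TestFirstOrder:
    def test_constant_region(self):
        f = first_order_features(np.full(20, 5.0))
        assert f["Variance"] == 0.0
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_hand_arithmetic(self):
        f = first_order_features(np.array([1.0, 2.0, 3.0, 4.0]), bin_width=1.0)
        assert f["Mean"] == 2.5
        assert f["Median"] == 2.5
        assert f["Range"] == 3.0
        assert f["Energy"] == 30.0
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(30 / 4))

    def test_total_energy_scales_with_voxel_volume(self):
        x = np.array([1.0, 2.0])
        assert first_order_features(x, voxel_volume=3.0)["TotalEnergy"] == pytest.approx(
            3.0 * first_order_features(x)["Energy"]
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            first_order_features(np.array([]))


class TestTextureFamilies:
    def test_family_sizes(self):
        sizes = {f: len(n) for f, n in FEATURE_NAMES.items()}
        assert sizes == {"firstorder": 18, "glcm": 24, "glrlm": 16,
                         "glszm": 16, "ngtdm": 5, "gldm": 14}
        assert N_FEATURES_PER_MAP == 93

    def test_glcm_hand_computed_alternating_pattern(self):
        """1D pattern 1,2,1,2: the symmetric co-occurrence matrix for the
        single in-line offset has counts {(1,2): 3, (2,1): 3}; contrast = 1."""
        vals = np.array([1.0, 2.0, 1.0, 2.0]).reshape(4, 1, 1)
        feats = texture_features(_droi(vals), "glcm")
        assert feats["Contrast"] == pytest.approx(1.0)
        assert feats["MaximumProbability"] == pytest.approx(0.5)
        assert feats["JointEntropy"] == pytest.approx(1.0)  # two equal cells

    def test_constant_patch_joint_entropy_zero(self):
        feats = texture_features(_droi(np.full((2, 2, 1), 3.0)), "glcm")
        assert feats["JointEntropy"] == 0.0
        assert feats["MCC"] == 1.0
        assert feats["Correlation"] == 1.0

    def test_single_voxel_defined_and_undefined_families(self):
        d = _droi(np.array([5.0]).reshape(1, 1, 1))
        for family in ("glrlm", "glszm", "gldm"):
            vals = texture_features(d, family)
            assert all(np.isfinite(v) for v in vals.values())
        for family in ("glcm", "ngtdm"):
            with pytest.raises(DegenerateROIError):
                texture_features(d, family)

    def test_glrlm_single_run(self):
        """A constant 1x1x4 line: every direction sees runs of the single
        level; the in-line direction has one run of length 4."""
        d = _droi(np.full((4, 1, 1), 2.0))
        feats = texture_features(d, "glrlm")
        assert feats["RunPercentage"] <= 1.0
        assert feats["GrayLevelVariance"] == 0.0

    def test_glszm_two_zones(self):
        vals = np.array([1.0, 1.0, 5.0, 5.0]).reshape(4, 1, 1)
        d = _droi(vals)
        feats = texture_features(d, "glszm")
        # two zones, each of size 2
        assert feats["ZonePercentage"] == pytest.approx(2 / 4)
        assert feats["LargeAreaEmphasis"] == pytest.approx(4.0)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            texture_features(_droi(np.ones((2, 2, 1))), "fractal")


class TestOracleAgreement:
    def test_random_rois_match_naive_oracle(self, rng):
        """Full-vector agreement with the independent loop-based oracle."""
        for _ in range(6):
            shape = tuple(rng.integers(4, 8, size=3))
            mask = rng.random(shape) < 0.7
            if mask.sum() < 8:
                continue
            vol = np.where(mask, rng.normal(50, 12, shape), np.nan)
            bw = float(rng.uniform(4, 10))
            mine = extract_feature_vector(
                ParametricMap("MRE", vol, ONES), Mask3D(mask, ONES), bin_width=bw
            )
            ref = naive_feature_vector(vol, mask, bw, voxel_volume=1.0)
            for name, expected in ref.items():
                got = mine[f"{name}.MRE"]
                assert got == pytest.approx(expected, rel=1e-6, abs=1e-9), name


class TestInvariances:
    def test_shift_by_bin_multiple_preserves_texture(self, rng):
        shape = (6, 6, 3)
        vol = rng.normal(40, 8, shape)
        mask = np.ones(shape, dtype=bool)
        bw = 5.0
        a = extract_feature_vector(ParametricMap("VE", vol, ONES), Mask3D(mask, ONES), bw)
        b = extract_feature_vector(
            ParametricMap("VE", vol + 3 * bw, ONES), Mask3D(mask, ONES), bw
        )
        for family in ("glcm", "glrlm", "glszm", "ngtdm", "gldm"):
            cols = [f"{family}_{n}.VE" for n in FEATURE_NAMES[family]]
            np.testing.assert_allclose(a[cols], b[cols], rtol=1e-9)

    def test_axis_permutation_preserves_features(self, rng):
        """Relabeling the traversal axes permutes the 13 directions among
        themselves, so direction-averaged features are unchanged."""
        shape = (5, 5, 5)
        vol = rng.normal(0, 1, shape)
        mask = rng.random(shape) < 0.8
        a = extract_feature_vector(ParametricMap("D", vol, ONES), Mask3D(mask, ONES), 0.5)
        b = extract_feature_vector(
            ParametricMap("D", vol.transpose(2, 0, 1), ONES),
            Mask3D(mask.transpose(2, 0, 1), ONES), 0.5,
        )
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), rtol=1e-9)


class TestAssembly:
    def _map_bundle(self, rng, names=ALL_MAP_NAMES):
        shape = (6, 6, 3)
        mask = Mask3D(np.ones(shape, dtype=bool), ONES)
        return {
            name: (ParametricMap(name, rng.normal(10, 3, shape), ONES), mask)
            for name in names
        }

    def test_twelve_maps_give_1116_features(self, rng):
        bundle = self._map_bundle(rng)
        bw = {name: 1.0 for name in ALL_MAP_NAMES}
        vec = extract_features_for_maps(bundle, bw)
        assert len(vec) == 1116

    def test_single_map_gives_93(self, rng):
        bundle = self._map_bundle(rng, names=("VP",))
        vec = extract_features_for_maps(bundle, {"VP": 1.0}, expected_maps=("VP",))
        assert len(vec) == 93
        assert "glcm_Idmn.VP" in vec.index

    def test_missing_map_named_in_error(self, rng):
        bundle = self._map_bundle(rng)
        del bundle["DSTAR"]
        with pytest.raises(ValueError, match="DSTAR"):
            extract_features_for_maps(bundle, {n: 1.0 for n in ALL_MAP_NAMES})

    def test_constant_map_yields_zero_dispersion_but_full_vector(self):
        shape = (4, 4, 2)
        mask = Mask3D(np.ones(shape, dtype=bool), ONES)
        pm = ParametricMap("F", np.full(shape, 0.3), ONES)
        vec = extract_feature_vector(pm, mask, bin_width=0.05)
        assert len(vec) == 93
        assert vec["firstorder_Variance.F"] == 0.0
        assert vec["glcm_Contrast.F"] == 0.0
        assert vec["firstorder_Entropy.F"] == 0.0

    def test_feature_table_shape_and_row_count(self, rng):
        records = []
        for lesion in ("les000", "les001"):
            for variant in ("original", "dil1", "ero1"):
                records.append((lesion, variant, self._map_bundle(rng)))
        table = extract_feature_table(records, {n: 1.0 for n in ALL_MAP_NAMES})
        assert table.shape == (6, 2 + 1116)
        assert list(table.columns[:2]) == ["lesion_id", "roi_variant"]

    def test_default_bin_widths_cover_all_maps(self):
        assert set(DEFAULT_BIN_WIDTHS) == set(ALL_MAP_NAMES)
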