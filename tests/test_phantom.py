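"""Phantom generator: geometry, forward signal models, cohort structure."""

import numpy as np
import pytest

from robustrad.diffusion import ivim_signal
from robustrad.kinetic import tofts_forward
from robustrad.phantom import (
    AcquisitionSpec,
    CohortSpec,
    LesionTruth,
    BASELINE_SIGNAL,
    make_cohort,
    make_lesion_mask,
    simulate_dce_series,
    simulate_dwi_series,
)

from conftest import SMALL_GRID, SMALL_SPACING


class TestLesionMask:
    def test_sphere_voxel_count_matches_brute_force(self):
        """Ellipsoid inclusion rule: voxel centers within ||x - c|| <= r."""
        r, c = 4.0, (10, 10, 10)
        mask = make_lesion_mask((21, 21, 21), (1, 1, 1), c, (r, r, r))
        count = 0
        for x in range(21):
            for y in range(21):
                for z in range(21):
                    if (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= r**2:
                        count += 1
        assert mask.voxel_count == count

    def test_half_spacing_radii_give_single_voxel(self):
        mask = make_lesion_mask((15, 15, 15), (1, 1, 1), (7, 7, 7), (0.5, 0.5, 0.5))
        assert mask.voxel_count == 1

    def test_border_violation_names_axis(self):
        with pytest.raises(ValueError, match="axis 2"):
            make_lesion_mask(SMALL_GRID, SMALL_SPACING, (12, 12, 6), (6.0, 6.0, 14.0))

    def test_radii_5mm_spacing_1mm_give_1cm_lesion(self):
        """Minimum lesion size: 5 mm radii = 1 cm diameter."""
        mask = make_lesion_mask((20, 20, 20), (1, 1, 1), (10, 10, 10), (5, 5, 5))
        x = np.nonzero(mask.data)[0]
        assert x.max() - x.min() + 1 == 11  # 10 mm span of voxel centers


class TestLesionTruth:
    @pytest.mark.parametrize("bad", [
        dict(ve=1.2), dict(vp=-0.1), dict(f_perf=1.5),
        dict(ve=0.7, vp=0.5),                 # ve + vp > 1
        dict(d_star=0.5e-3),                  # d_star <= d
        dict(radii=(4.0, 6.0, 6.0)),          # sub-centimeter lesion
        dict(class_label="cyst"),
    ])
    def test_invariants_rejected(self, bad):
        kwargs = dict(
            class_label="adenoma", ktrans=0.1, ve=0.3, vp=0.02,
            d_true=1.0e-3, d_star=8e-3, f_perf=0.1,
            center=(12, 12, 6), radii=(6, 6, 6),
        )
        kwargs.update(bad)
        with pytest.raises(ValueError):
            LesionTruth(**kwargs)


class TestAcquisitionSpec:
    def test_defaults_match_protocol(self):
        acq = AcquisitionSpec()
        assert acq.dce_n_frames == 11
        assert acq.dce_dt == 38.0
        assert list(acq.b_values) == [0, 10, 20, 30, 50, 80, 100, 200, 300, 400, 800]

    def test_invalid_b_values_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionSpec(dwi_b_values=(10, 20, 800))
        with pytest.raises(ValueError):
            AcquisitionSpec(dwi_b_values=(0, 20, 20, 800))


class TestDCESimulation:
    def test_no_exchange_gives_flat_lesion_signal(self, small_acq_noiseless, aif):
        truth = LesionTruth("adenoma", 0.0, 0.3, 0.0, 1e-3, 8e-3, 0.1,
                            (12, 12, 6), (6, 6, 7))
        series = simulate_dce_series(truth, small_acq_noiseless, aif, seed=0)
        lesion = series.data[12, 12, 6]
        assert np.allclose(lesion, lesion[0])

    def test_precontrast_frame_is_baseline_exactly(self, small_acq_noiseless,
                                                   canonical_truth, aif):
        series = simulate_dce_series(canonical_truth, small_acq_noiseless, aif, seed=0)
        assert np.allclose(series.data[..., 0], BASELINE_SIGNAL)

    def test_noiseless_voxel_curve_equals_forward_model(self, small_acq_noiseless,
                                                        canonical_truth, aif):
        """Closed loop with the kinetic forward model."""
        alpha = 4.0
        series = simulate_dce_series(canonical_truth, small_acq_noiseless, aif,
                                     seed=0, alpha=alpha)
        t = canonical_truth
        ct = tofts_forward((t.ktrans, t.ve, t.vp), aif, series.axis)
        expected = BASELINE_SIGNAL * (1 + alpha * ct)
        np.testing.assert_allclose(series.data[12, 12, 6], expected, rtol=1e-6)

    def test_background_stays_at_baseline(self, small_acq_noiseless,
                                          canonical_truth, aif):
        series = simulate_dce_series(canonical_truth, small_acq_noiseless, aif, seed=0)
        assert np.allclose(series.data[1, 1, 1], BASELINE_SIGNAL)


class TestDWISimulation:
    def test_b0_equals_baseline_noiseless(self, small_acq_noiseless, canonical_truth):
        series = simulate_dwi_series(canonical_truth, small_acq_noiseless, seed=0)
        assert series.data[12, 12, 6, 0] == pytest.approx(BASELINE_SIGNAL)

    def test_pure_diffusion_is_loglinear(self, small_acq_noiseless):
        truth = LesionTruth("adenoma", 0.1, 0.3, 0.02, 1.2e-3, 8e-3, 0.0,
                            (12, 12, 6), (6, 6, 7))
        series = simulate_dwi_series(truth, small_acq_noiseless, seed=0)
        b = series.axis
        logs = np.log(series.data[12, 12, 6].astype(float))
        slope = np.polyfit(b, logs, 1)[0]
        assert slope == pytest.approx(-1.2e-3, rel=1e-5)

    def test_biexponential_value_at_b800(self, small_acq_noiseless, canonical_truth):
        """Hand evaluation of the biexponential at the strongest weighting."""
        series = simulate_dwi_series(canonical_truth, small_acq_noiseless, seed=0)
        expected = 0.15 * np.exp(-800 * 10e-3) + 0.85 * np.exp(-800 * 1.0e-3)
        assert series.data[12, 12, 6, -1] / BASELINE_SIGNAL == pytest.approx(
            expected, rel=1e-5
        )
        # forward helper agrees with the hand value too
        assert ivim_signal(800, 1.0, 1.0e-3, 10e-3, 0.15) == pytest.approx(expected)


class TestCohort:
    def _small_spec(self, **kw):
        return CohortSpec(rng_seed=3, **kw)

    def test_default_cohort_counts(self, small_acq_noisy):
        lesions, truth = make_cohort(self._small_spec(), small_acq_noisy)
        assert len(lesions) == 43
        counts = truth["class"].value_counts()
        assert counts["malignant"] == 18
        assert counts["adenoma"] + counts["warthin"] == 25

    def test_one_per_class(self, small_acq_noisy):
        spec = self._small_spec(n_per_class={c: 1 for c in ("adenoma", "warthin", "malignant")})
        lesions, truth = make_cohort(spec, small_acq_noisy)
        assert len(lesions) == 3
        assert set(truth["class"]) == {"adenoma", "warthin", "malignant"}

    def test_same_seed_reproduces_truth_table(self, small_acq_noisy):
        spec = self._small_spec(n_per_class={"adenoma": 2, "warthin": 1, "malignant": 2})
        _, t1 = make_cohort(spec, small_acq_noisy)
        _, t2 = make_cohort(spec, small_acq_noisy)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_same_seed_reproduces_images(self, small_acq_noisy):
        spec = self._small_spec(n_per_class={"adenoma": 1, "warthin": 1, "malignant": 1})
        l1, _ = make_cohort(spec, small_acq_noisy)
        l2, _ = make_cohort(spec, small_acq_noisy)
        for a, b in zip(l1, l2):
            np.testing.assert_array_equal(a.dce.data, b.dce.data)
            np.testing.assert_array_equal(a.dwi.data, b.dwi.data)

    def test_impossible_distribution_raises_after_resampling(self, small_acq_noisy):
        dists = {c: dict(d) for c, d in
                 self._small_spec().class_distributions.items()}
        dists["adenoma"]["ve"] = (0.9, 0.0)
        dists["adenoma"]["vp"] = (0.9, 0.0)   # ve + vp > 1 on every draw
        spec = CohortSpec(n_per_class={"adenoma": 1, "warthin": 1, "malignant": 1},
                          class_distributions=dists, rng_seed=0)
        with pytest.raises(RuntimeError, match="100 attempts"):
            make_cohort(spec, small_acq_noisy)

    def test_class_counts_validated(self):
        with pytest.raises(ValueError):
            CohortSpec(n_per_class={"adenoma": 0, "warthin": 1, "malignant": 1})
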