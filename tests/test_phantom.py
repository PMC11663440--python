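"""Synthetic-data generator: closed-form truth, pore planting, cohorts."""

import math

import numpy as np
import pandas as pd
import pytest

from bonecsg.growth import GrowthCurve, fit_growth_curve
from bonecsg.phantom import (
    CohortSpec,
    MedullaryTrajectory,
    PhantomSpec,
    PorePackingError,
    SectionTruth,
    make_cohort,
    make_phantom_volume,
    make_section_phantom,
    section_truth_at,
    simulate_growth_pairs,
)
from bonecsg.section import section_geometry

CURVE = GrowthCurve((67.75, 34.58, -3.21, 0.133), (0.0, 13.0), (60.0, 270.0))


class TestClosedFormTruth:
    def test_circular_annulus_truth(self):
        t = SectionTruth.from_annulus(10.0, 10.0, 5.0, 5.0)
        assert t.TA_mm2 == pytest.approx(314.159, abs=1e-3)
        assert t.MA_mm2 == pytest.approx(78.540, abs=1e-3)
        assert t.CA_mm2 == pytest.approx(235.619, abs=1e-3)
        assert t.medullary_index == pytest.approx(0.25)
        assert t.Imax_mm4 / t.Imin_mm4 == pytest.approx(1.0)

    def test_elliptical_annulus_truth(self):
        t = SectionTruth.from_annulus(10.0, 5.0, 6.0, 3.0)
        assert t.Ix_mm4 == pytest.approx(math.pi * (10 * 125 - 6 * 27) / 4)
        assert t.Ix_mm4 == pytest.approx(854.51, abs=0.01)
        assert t.Iy_mm4 == pytest.approx(3417.96, abs=0.1)
        assert t.Ix_mm4 / t.Iy_mm4 == pytest.approx(0.25)
        assert t.Imax_mm4 / t.Imin_mm4 == pytest.approx(4.0)

    @pytest.mark.parametrize("frac", [0.2, 0.35, 0.5, 0.65, 0.8])
    def test_truth_identity_ta_equals_ca_plus_ma(self, frac):
        t = section_truth_at(PhantomSpec(), frac)
        assert t.TA_mm2 == pytest.approx(t.CA_mm2 + t.MA_mm2, rel=1e-12)
        assert t.Imax_mm4 >= t.Imin_mm4 > 0


class TestSectionPhantom:
    def test_degenerate_cavity_yields_zero_medullary(self):
        _, t = make_section_phantom((10.0, 10.0), (0.0, 0.0))
        assert t.MA_mm2 == 0.0
        assert t.medullary_index == 0.0

    def test_pixel_count_area_matches_closed_form(self):
        sec, _ = make_section_phantom((10.0, 10.0), (5.0, 5.0), pixel_size_mm=0.05)
        ta = (sec.intensities > 110).sum() * 0.05**2  # cortex only
        ma_truth = math.pi * 25
        assert ta == pytest.approx(math.pi * 100 - ma_truth, rel=0.01)

    def test_planted_porosity_within_half_percentage_point(self):
        _, t = make_section_phantom((10.0, 8.0), (5.0, 4.0), pore_fraction=0.10, seed=1)
        assert 0.095 <= t.porosity_index <= 0.105

    def test_infeasible_pore_radius_raises(self):
        with pytest.raises(PorePackingError):
            make_section_phantom(
                (10.0, 8.0), (9.5, 7.5), pore_fraction=0.10, pore_radius_mm=0.5
            )

    def test_discretization_error_shrinks_with_pixel_size(self):
        errs = {}
        for px in (0.1, 0.025):
            sec, truth = make_section_phantom((10.0, 5.0), (6.0, 3.0),
                                              pixel_size_mm=px, seed=2)
            g = section_geometry(sec)
            errs[px] = abs(g.TA_mm2 / truth.TA_mm2 - 1)
        assert errs[0.025] <= 0.5 * errs[0.1]


class TestVolumePhantom:
    def test_waisted_sections_differ_and_match_truth(self, small_phantom):
        spec, volume, truths = small_phantom
        tas = [t.TA_mm2 for t in truths.values()]
        assert max(tas) - min(tas) > 0.02 * max(tas)
        # per-slice voxel tally against the analytic annulus area
        data = np.asarray(volume.intensities)
        n_z = int(round(spec.length_mm / spec.voxel_size_mm))
        for frac, t in truths.items():
            k = 3 + int(math.floor(frac * (n_z - 1) + 0.5))  # z padding = 3
            ca_vox = (data[k] > 110).sum() * spec.voxel_size_mm**2
            assert ca_vox == pytest.approx(t.CA_mm2, rel=0.02)

    def test_pore_packing_error_propagates_in_3d(self):
        spec = PhantomSpec(length_mm=10.0, voxel_size_mm=0.2, pore_fraction=0.35,
                           pore_radius_mm=1.5)
        with pytest.raises(PorePackingError):
            make_phantom_volume(spec)

    def test_volume_generation_is_deterministic(self):
        spec = PhantomSpec(length_mm=12.0, voxel_size_mm=0.25, pore_fraction=0.05,
                           seed=5)
        v1, t1 = make_phantom_volume(spec)
        v2, t2 = make_phantom_volume(spec)
        assert np.array_equal(v1.intensities, v2.intensities)
        assert t1 == t2


class TestCohorts:
    def test_cohort_is_pure_function_of_spec_and_seed(self):
        spec = CohortSpec(n_individuals=12, seed=42)
        c1, c2 = make_cohort(spec), make_cohort(spec)
        pd.testing.assert_frame_equal(c1.metadata, c2.metadata)
        pd.testing.assert_frame_equal(c1.truth, c2.truth)

    def test_noise_free_cohort_sits_exactly_on_trajectories(self):
        spec = CohortSpec(
            n_individuals=10, seed=3,
            noise_sds={"medullary": 0.0, "porosity": 0.0, "shape": 0.0, "length": 0.0},
        )
        data = make_cohort(spec)
        merged = data.truth.merge(data.metadata, on="specimen_id")
        ages = merged["age_years_x"].to_numpy()
        expect_m = np.asarray(spec.medullary_trajectory(ages))
        np.testing.assert_allclose(merged["medullary_index"], expect_m, rtol=1e-12)
        expect_q = np.asarray(spec.porosity_trajectory(ages))
        np.testing.assert_allclose(merged["porosity_index"], expect_q, rtol=1e-12)

    def test_default_medullary_trajectory_peaks_at_peak_age(self):
        traj = MedullaryTrajectory()
        grid = np.linspace(0.0, 13.0, 2000)
        vals = np.asarray(traj(grid))
        peak = grid[np.argmax(vals)]
        assert peak == pytest.approx(traj.peak_age, abs=0.02)
        assert vals[0] < vals.max() and vals[-1] < vals.max()  # interior maximum

    def test_cohort_lengths_follow_growth_curve(self):
        spec = CohortSpec(
            n_individuals=15, seed=8,
            noise_sds={"medullary": 0.0, "porosity": 0.0, "shape": 0.0, "length": 0.0},
        )
        meta = make_cohort(spec).metadata
        np.testing.assert_allclose(
            meta["femur_length_mm"],
            np.asarray(spec.growth_curve(meta["age_years"].to_numpy())),
            rtol=1e-12,
        )

    def test_realized_volumes_match_request(self):
        spec = CohortSpec(n_individuals=2, seed=1, voxel_size_mm=0.3,
                          age_range_years=(4.0, 8.0))
        data = make_cohort(spec, realize_volumes=True, truth_fractions=(0.5,))
        assert len(data.volumes) == 2
        assert all(v.intensities.ndim == 3 for v in data.volumes)


class TestGrowthPairs:
    def test_noise_free_pairs_lie_on_the_cubic(self):
        df = simulate_growth_pairs(CURVE, 16, 0.0, seed=0)
        np.testing.assert_allclose(
            df["femur_length_mm"], np.asarray(CURVE(df["age_years"].to_numpy())),
            rtol=1e-12,
        )

    def test_reproducible_under_seed(self):
        a = simulate_growth_pairs(CURVE, 10, 3.0, seed=7)
        b = simulate_growth_pairs(CURVE, 10, 3.0, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            simulate_growth_pairs(CURVE, 3, 1.0)

    def test_refit_recovers_coefficients_as_noise_vanishes(self):
        errs = []
        for noise in (5.0, 0.5, 0.005):
            df = simulate_growth_pairs(CURVE, 16, noise, seed=5)
            fit = fit_growth_curve(df["age_years"], df["femur_length_mm"])
            errs.append(
                np.linalg.norm(np.array(fit.coefficients) - np.array(CURVE.coefficients))
            )
        assert errs[2] < errs[1] < errs[0]
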