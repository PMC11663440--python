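"""Single-section geometry: thresholding, contours, areas, moments, porosity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonecsg.phantom import make_section_phantom
from bonecsg.section import (
    CrossSectionImage,
    SegmentationError,
    cortical_porosity,
    compute_areas,
    endocortical_ellipse,
    minimum_threshold,
    periosteal_contour,
    second_moments,
    section_geometry,
)

PX = 0.05


class TestMinimumThreshold:
    def test_two_spike_histogram_ties_to_lower_intensity(self):
        h = np.zeros(256)
        h[10], h[240] = 500, 800
        assert minimum_threshold(h) == 11

    def test_constant_histogram_has_no_bimodal_structure(self):
        with pytest.raises(SegmentationError):
            minimum_threshold(np.full(256, 7.0))

    def test_bimodal_gaussian_histogram_classifies_bone_correctly(self):
        rng = np.random.default_rng(0)
        bone = np.clip(rng.normal(200, 8, 40_000), 0, 255).astype(int)
        backgr = np.clip(rng.normal(30, 8, 60_000), 0, 255).astype(int)
        h = np.bincount(np.r_[bone, backgr], minlength=256)
        thr = minimum_threshold(h)
        assert 60 < thr < 180
        assert (bone > thr).mean() >= 0.99
        assert (backgr <= thr).mean() >= 0.99


class TestContoursAndAreas:
    def test_filled_circle_area_matches_closed_form(self):
        sec, truth = make_section_phantom((10.0, 10.0), (0.0, 0.0), pixel_size_mm=PX)
        contour = periosteal_contour(sec)
        assert contour.enclosed_area_mm2 == pytest.approx(math.pi * 100, rel=0.01)

    def test_interior_pores_do_not_alter_the_outer_contour(self):
        solid, _ = make_section_phantom((10.0, 8.0), (5.0, 4.0), pixel_size_mm=PX, seed=5)
        porous, _ = make_section_phantom(
            (10.0, 8.0), (5.0, 4.0), pore_fraction=0.10, pixel_size_mm=PX, seed=5
        )
        m_solid = periosteal_contour(solid).mask
        m_porous = periosteal_contour(porous).mask
        assert np.array_equal(m_solid, m_porous)

    def test_two_disjoint_blobs_keep_only_the_larger(self):
        img = np.full((120, 200), 20, dtype=np.uint8)
        img[30:90, 20:100] = 200  # large block
        img[50:60, 150:170] = 200  # small satellite
        sec = CrossSectionImage(img, 0.1)
        contour = periosteal_contour(sec)
        assert contour.mask.sum() == 60 * 80

    def test_annulus_areas_match_closed_forms(self):
        sec, truth = make_section_phantom((10.0, 5.0), (6.0, 3.0), pixel_size_mm=PX)
        contour = periosteal_contour(sec)
        ellipse = endocortical_ellipse(sec, contour)
        ta, ma, ca = compute_areas(contour, ellipse, PX)
        assert ta == pytest.approx(157.0796, rel=0.01)
        assert ma == pytest.approx(56.5487, rel=0.02)
        assert ca == pytest.approx(100.5310, rel=0.02)
        a, b = ellipse.semi_axes_mm
        assert a == pytest.approx(6.0, rel=0.02)
        assert b == pytest.approx(3.0, rel=0.02)

    def test_solid_section_yields_zero_medullary_area(self):
        sec, _ = make_section_phantom((10.0, 10.0), (0.0, 0.0), pixel_size_mm=PX)
        geom = section_geometry(sec)
        assert geom.MA_mm2 == 0.0
        assert geom.medullary_index == 0.0

    def test_scalloped_endocortical_border_still_recovers_cavity_ellipse(self):
        # pores coalescing at the endocortical margin scallop the cavity
        # boundary; the conic fit should still land near the unscalloped truth
        sec, truth = make_section_phantom((10.0, 8.0), (6.0, 4.0), pixel_size_mm=PX, seed=3)
        img = sec.intensities.copy()
        rng = np.random.default_rng(3)
        n = img.shape[0]
        c = (n - 1) / 2.0
        scallop_area = 0.0
        while scallop_area < 0.10 * math.pi * 24.0:  # ~10% of cavity area
            t = rng.uniform(0, 2 * math.pi)
            x, y = 6.0 * math.cos(t), 4.0 * math.sin(t)
            rr = rng.uniform(0.2, 0.35)
            yy, xx = np.mgrid[0:n, 0:n]
            disk = ((xx - c) * PX - x) ** 2 + ((yy - c) * PX - y) ** 2 <= rr**2
            img[disk] = 20
            scallop_area += math.pi * rr**2
        scalloped = CrossSectionImage(img, PX)
        geom = section_geometry(scalloped)
        assert geom.MA_mm2 == pytest.approx(truth.MA_mm2, rel=0.05)


class TestSecondMoments:
    def test_centred_square_is_exact(self):
        region = np.zeros((100, 100), dtype=bool)
        region[40:60, 40:60] = True  # 2 mm square at 0.1 mm pixels
        ix, iy, ixy, imax, imin, theta = second_moments(region, 0.1)
        assert ix == pytest.approx(2**4 / 12, rel=1e-9)
        assert iy == pytest.approx(2**4 / 12, rel=1e-9)
        assert ixy == pytest.approx(0.0, abs=1e-9)
        assert imax / imin == pytest.approx(1.0, rel=1e-9)

    def test_elliptical_annulus_matches_closed_forms(self):
        sec, truth = make_section_phantom((10.0, 5.0), (6.0, 3.0), pixel_size_mm=PX)
        geom = section_geometry(sec)
        assert geom.Ix_mm4 == pytest.approx(854.513, rel=0.02)
        assert geom.Iy_mm4 == pytest.approx(3418.053, rel=0.02)
        assert geom.imax_imin_ratio == pytest.approx(4.0, rel=0.02)
        assert geom.ix_iy_ratio == pytest.approx(0.25, rel=0.02)
        assert geom.theta_deg == pytest.approx(0.0, abs=1.0)

    def test_in_plane_rotation_preserves_principal_moments(self):
        _, truth = make_section_phantom((10.0, 5.0), (6.0, 3.0), pixel_size_mm=PX)
        sec_rot, _ = make_section_phantom(
            (10.0, 5.0), (6.0, 3.0), pixel_size_mm=PX, rotation_deg=30.0
        )
        geom = section_geometry(sec_rot)
        assert geom.Imax_mm4 == pytest.approx(truth.Imax_mm4, rel=0.01)
        assert geom.Imin_mm4 == pytest.approx(truth.Imin_mm4, rel=0.01)
        assert abs(abs(geom.theta_deg) - 30.0) < 2.0

    def test_single_pixel_region_is_degenerate(self):
        region = np.zeros((10, 10), dtype=bool)
        region[5, 5] = True
        with pytest.raises(SegmentationError):
            second_moments(region, 0.1)


class TestPorosity:
    def test_pore_free_section_has_zero_porosity(self):
        sec, _ = make_section_phantom((10.0, 8.0), (5.0, 4.0), pixel_size_mm=PX)
        geom = section_geometry(sec)
        assert geom.CPA_mm2 == 0.0
        assert geom.porosity_index == 0.0

    def test_planted_pore_fraction_is_recovered(self):
        sec, truth = make_section_phantom(
            (10.0, 8.0), (5.0, 4.0), pore_fraction=0.10, pixel_size_mm=PX, seed=9
        )
        geom = section_geometry(sec)
        assert 0.08 <= geom.porosity_index <= 0.12
        assert truth.porosity_index == pytest.approx(0.10, abs=0.005)

    def test_porosity_increases_with_planted_fraction(self):
        measured = []
        for pf in (0.02, 0.05, 0.10, 0.20):
            sec, _ = make_section_phantom(
                (10.0, 8.0), (5.0, 4.0), pore_fraction=pf, pixel_size_mm=PX, seed=13
            )
            measured.append(section_geometry(sec).porosity_index)
        assert all(np.diff(measured) > 0)


class TestSectionGeometryOrchestration:
    def test_full_record_matches_truth_within_budget(self):
        sec, truth = make_section_phantom(
            (11.0, 7.0), (6.0, 4.0), pore_fraction=0.05, pixel_size_mm=PX,
            noise_sd=4.0, seed=21,
        )
        geom = section_geometry(sec)
        assert geom.TA_mm2 == pytest.approx(truth.TA_mm2, rel=0.02)
        assert geom.CA_mm2 == pytest.approx(truth.CA_mm2, rel=0.02)
        assert geom.MA_mm2 == pytest.approx(truth.MA_mm2, rel=0.05)
        assert geom.Ix_mm4 == pytest.approx(truth.Ix_mm4, rel=0.02)
        assert geom.Iy_mm4 == pytest.approx(truth.Iy_mm4, rel=0.02)
        assert geom.porosity_index == pytest.approx(truth.porosity_index, abs=0.01)

    def test_deterministic_for_identical_input(self):
        sec, _ = make_section_phantom((9.0, 6.0), (4.0, 3.0), pore_fraction=0.08,
                                      pixel_size_mm=PX, seed=2)
        assert section_geometry(sec) == section_geometry(sec)

    def test_circular_section_is_nearly_isotropic(self):
        sec, _ = make_section_phantom((9.0, 9.0), (4.0, 4.0), pixel_size_mm=PX)
        geom = section_geometry(sec)
        assert 1.0 <= geom.imax_imin_ratio <= 1.05

    def test_trace_mode_agrees_with_ellipse_mode_on_clean_annulus(self):
        sec, truth = make_section_phantom((10.0, 7.0), (5.0, 3.5), pixel_size_mm=PX)
        g_ell = section_geometry(sec, endocortical="ellipse")
        g_tr = section_geometry(sec, endocortical="trace")
        assert g_tr.MA_mm2 == pytest.approx(g_ell.MA_mm2, rel=0.02)

    def test_scale_equivariance_of_mm_outputs(self):
        fine, _ = make_section_phantom((10.0, 7.0), (5.0, 3.5), pixel_size_mm=0.05)
        coarse, _ = make_section_phantom((10.0, 7.0), (5.0, 3.5), pixel_size_mm=0.1)
        gf, gc = section_geometry(fine), section_geometry(coarse)
        for attr in ("TA_mm2", "MA_mm2", "Ix_mm4", "Iy_mm4"):
            assert getattr(gc, attr) == pytest.approx(getattr(gf, attr), rel=0.03)


@settings(max_examples=12, deadline=None, derandomize=True)
@given(
    a=st.floats(6.0, 12.0),
    b_ratio=st.floats(0.45, 1.0),
    rho=st.floats(0.3, 0.7),
    pf=st.sampled_from([0.0, 0.05, 0.12]),
    seed=st.integers(0, 10_000),
)
def test_structural_identities_hold_for_any_section(a, b_ratio, rho, pf, seed):
    """TA = CA + MA exactly; Imax + Imin = Ix + Iy; ratios and indices in range."""
    b = a * b_ratio
    sec, _ = make_section_phantom(
        (a, b), (rho * a, rho * b), pore_fraction=pf, pixel_size_mm=0.1,
        pore_radius_mm=0.25, seed=seed,
    )
    g = section_geometry(sec)
    assert g.TA_mm2 == pytest.approx(g.CA_mm2 + g.MA_mm2, rel=1e-12)
    assert g.Imax_mm4 + g.Imin_mm4 == pytest.approx(g.Ix_mm4 + g.Iy_mm4, rel=1e-9)
    assert g.Imax_mm4 >= g.Imin_mm4 > 0
    assert g.imax_imin_ratio >= 1.0
    assert 0.0 <= g.medullary_index <= 1.0
    assert 0.0 <= g.porosity_index <= 1.0
    assert -90.0 < g.theta_deg <= 90.0
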