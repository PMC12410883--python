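"""Ellipse fitting, diameter estimators, g-ratio and cut-angle invariance."""

import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from axonmetrics.morphometry import (
    DegenerateRegionError,
    equivalent_circle_diameter,
    fit_ellipse,
    measure_fiber,
    measure_instances,
    myelin_thickness_skeleton,
    records_to_frame,
)
from axonmetrics.phantom import FiberSpec, rasterize

from conftest import PX_UM, disk_mask

PX_NM = 17.28


def _ellipse_mask(shape, center, r_radius, c_radius, rotation=0.0):
    m = np.zeros(shape, bool)
    rr, cc = draw_ellipse(*center, r_radius, c_radius, rotation=rotation)
    m[rr, cc] = True
    return m


class TestFitEllipse:
    def test_disk_diameter(self):
        m = disk_mask((101, 101), (50, 50), 20)
        fit = fit_ellipse(m, PX_NM)
        # 40 px at 17.28 nm/px ~ 0.691 µm, within 2 px-equivalents
        assert fit.minor_axis_um == pytest.approx(0.691, abs=2 * PX_UM)
        assert fit.major_axis_um == pytest.approx(0.691, abs=2 * PX_UM)

    def test_axis_ratio_two_eccentricity(self):
        m = _ellipse_mask((201, 201), (100, 100), 20, 40)
        fit = fit_ellipse(m, PX_NM)
        assert fit.eccentricity == pytest.approx(np.sqrt(1 - 0.25), abs=0.01)
        # identity ecc = sqrt(1 - (minor/major)^2)
        ratio = fit.minor_axis_um / fit.major_axis_um
        assert fit.eccentricity == pytest.approx(np.sqrt(1 - ratio**2), abs=1e-9)

    def test_orientation_convention(self):
        m = _ellipse_mask((201, 201), (100, 100), 20, 40)  # major along x
        assert abs(fit_ellipse(m, PX_NM).orientation_deg) < 1.5

    def test_degenerate_region_error(self):
        m = np.zeros((10, 10), bool)
        m[5, 5] = True
        with pytest.raises(DegenerateRegionError):
            fit_ellipse(m, PX_NM, min_region_px=10)


class TestEquivalentCircleDiameter:
    def test_disk_identity(self):
        m = disk_mask((101, 101), (50, 50), 20)
        assert equivalent_circle_diameter(m, PX_NM) / PX_UM == pytest.approx(40, abs=1)

    def test_ellipse_geometric_mean(self):
        m = _ellipse_mask((201, 201), (100, 100), 20, 40)
        # 2*sqrt(20*40) ~ 56.6 px
        assert equivalent_circle_diameter(m, PX_NM) / PX_UM == pytest.approx(56.6, abs=1)

    def test_always_at_least_minor_axis(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            b = rng.integers(8, 25)
            a = rng.integers(b, 50)
            rot = rng.uniform(0, np.pi)
            m = _ellipse_mask((221, 221), (110, 110), b, a, rot)
            fit = fit_ellipse(m, PX_NM)
            assert equivalent_circle_diameter(m, PX_NM) >= fit.minor_axis_um - 1e-9

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            equivalent_circle_diameter(np.zeros((5, 5), bool), PX_NM)


class TestMyelinThicknessSkeleton:
    def test_annulus_thickness(self):
        m = disk_mask((101, 101), (50, 50), 35) & ~disk_mask((101, 101), (50, 50), 20)
        t = myelin_thickness_skeleton(m, PX_NM)
        assert t / PX_UM == pytest.approx(15, abs=2)

    def test_one_px_ring_flagged_missing(self):
        m = disk_mask((61, 61), (30, 30), 15) & ~disk_mask((61, 61), (30, 30), 14)
        assert myelin_thickness_skeleton(m, PX_NM) is None

    def test_robust_to_missing_sector(self):
        full = disk_mask((101, 101), (50, 50), 35) & ~disk_mask((101, 101), (50, 50), 20)
        ys, xs = np.nonzero(full)
        ang = np.degrees(np.arctan2(ys - 50, xs - 50)) % 360
        broken = full.copy()
        broken[ys[ang < 90], xs[ang < 90]] = False
        t_full = myelin_thickness_skeleton(full, PX_NM)
        t_broken = myelin_thickness_skeleton(broken, PX_NM)
        assert t_broken == pytest.approx(t_full, abs=2 * PX_UM)


class TestMeasureFiber:
    def test_orthogonal_cut_g_ratio(self):
        spec = FiberSpec(1, 0.4, 0.2, 0.0, (6.0, 6.0))
        _, inst, _ = rasterize([spec], (700, 700))
        rec = measure_fiber(1, inst)
        assert rec.g_ratio == pytest.approx(0.4 / 0.6, abs=0.02)

    def test_g_ratio_invariant_to_cut_angle(self):
        g0 = None
        for angle in (0.0, 50.0):
            spec = FiberSpec(1, 0.4, 0.2, angle, (8.0, 8.0))
            _, inst, _ = rasterize([spec], (1000, 1000))
            rec = measure_fiber(1, inst)
            if g0 is None:
                g0 = rec.g_ratio
            else:
                assert rec.g_ratio == pytest.approx(g0, abs=0.02)

    def test_missing_id_is_error(self):
        spec = FiberSpec(1, 0.4, 0.2, 0.0, (6.0, 6.0))
        _, inst, _ = rasterize([spec], (700, 700))
        with pytest.raises(ValueError, match="no_axon"):
            measure_fiber(99, inst)

    def test_outer_minor_consistency_with_alternative_estimators(self):
        # ellipse outer diameter vs equivalent-circle axon + 2x skeleton
        # thickness on an undegraded circular fiber
        spec = FiberSpec(1, 0.45, 0.25, 0.0, (8.0, 8.0))
        _, inst, _ = rasterize([spec], (1000, 1000))
        rec = measure_fiber(1, inst)
        alt = rec.d_eq_axon_um + 2 * rec.myelin_thickness_skel_um
        assert rec.outer_minor_um == pytest.approx(alt, rel=0.05)


class TestMeasureInstances:
    def test_population_medians_match_truth(self, phantom_50, measured_50):
        _, _, _, truth = phantom_50
        df = records_to_frame(measured_50)
        assert df["axon_minor_um"].median() == pytest.approx(
            (2 * truth.axon_radius_um).median(), abs=2 * PX_UM
        )
        assert df["g_ratio"].median() == pytest.approx(
            truth.g_ratio_true.median(), abs=0.02
        )

    def test_minor_axis_invariance_major_axis_growth(self):
        angles = np.arange(0.0, 61.0, 10.0)
        specs = [
            FiberSpec(i + 1, 0.4, 0.2, float(a), (3.0 + 5.0 * i, 6.0))
            for i, a in enumerate(angles)
        ]
        _, inst, truth = rasterize(specs, (700, 2300))
        for i, a in enumerate(angles):
            rec = measure_fiber(i + 1, inst)
            assert rec.axon_minor_um == pytest.approx(0.8, abs=2 * PX_UM)
            expected_major = 0.8 / np.cos(np.radians(a))
            assert rec.axon_fit.major_axis_um == pytest.approx(
                expected_major, rel=0.05
            )

    def test_frame_columns(self, measured_50):
        df = records_to_frame(measured_50)
        assert len(df) == 50
        assert df["g_ratio"].between(0, 1).all()
        # g-ratio is the ratio of minor axes, exactly
        np.testing.assert_allclose(
            df["g_ratio"], df["axon_minor_um"] / df["outer_minor_um"], rtol=1e-9
        )
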