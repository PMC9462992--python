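"""Ellipse fitting, tangent construction and angle computation oracles."""

import numpy as np
import pytest
from skimage.measure import EllipseModel

from aopmeter import geometry, phantom
from aopmeter.geometry import (Ellipse, GeometryError, compute_aop, fit_ellipse,
                               mask_boundary, measure, select_tangent,
                               tangent_points)


def sample_ellipse_points(e: Ellipse, n=200):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.array([e.point_at(ti) for ti in t])


class TestEllipseRepresentation:
    def test_conic_geometric_round_trip(self):
        e = Ellipse(center=(3.2, -1.7), a=5.5, b=2.1, angle_deg=37.0)
        back = Ellipse.from_conic(e.conic)
        assert np.allclose(back.center, e.center, atol=1e-9)
        assert abs(back.a - e.a) < 1e-9 and abs(back.b - e.b) < 1e-9
        assert abs((back.angle_deg - e.angle_deg + 90) % 180 - 90) < 1e-9

    def test_sign_convention_interior_negative(self):
        e = Ellipse(center=(0, 0), a=2, b=1, angle_deg=0)
        assert e.evaluate((0, 0)) < 0 < e.evaluate((5, 5))

    def test_invalid_axes_rejected(self):
        with pytest.raises(GeometryError):
            Ellipse(center=(0, 0), a=1, b=2, angle_deg=0)


class TestFitEllipse:
    def test_unit_circle_identity(self):
        pts = sample_ellipse_points(Ellipse(center=(0, 0), a=1, b=1, angle_deg=0), 12)
        fit = fit_ellipse(pts)
        assert np.allclose(fit.center, (0, 0), atol=1e-9)
        assert abs(fit.a - 1) < 1e-9 and abs(fit.b - 1) < 1e-9

    @pytest.mark.parametrize("center,a,b,angle", [
        ((3, 4), 5, 2, 30), ((-10, 7), 8, 7.5, 120), ((0.5, 0.5), 2, 0.5, 91)])
    def test_noiseless_round_trip(self, center, a, b, angle):
        true = Ellipse(center=center, a=a, b=b, angle_deg=angle)
        fit = fit_ellipse(sample_ellipse_points(true))
        assert np.allclose(fit.center, center, atol=1e-6)
        assert abs(fit.a - a) < 1e-6 and abs(fit.b - b) < 1e-6
        assert abs((fit.angle_deg - angle + 90) % 180 - 90) < 1e-6

    def test_algebraic_residual_noiseless(self):
        true = Ellipse(center=(3, 4), a=5, b=2, angle_deg=30)
        pts = sample_ellipse_points(true)
        fit = fit_ellipse(pts)
        res = np.array([fit.evaluate(p) for p in pts])
        assert np.abs(res).max() < 1e-9

    def test_matches_independent_skimage_fit(self, rng):
        """Cross-check against the independently implemented estimator."""
        true = Ellipse(center=(40, 30), a=18, b=11, angle_deg=55)
        pts = sample_ellipse_points(true, 150)
        pts_noisy = pts + rng.normal(0, 0.05, pts.shape)
        ours = fit_ellipse(pts_noisy)
        m = EllipseModel()
        assert m.estimate(pts_noisy)
        xc, yc, a, b, theta = m.params
        if b > a:
            a, b = b, a
            theta += np.pi / 2
        assert np.allclose(ours.center, (xc, yc), atol=0.05)
        assert abs(ours.a - a) < 0.05 and abs(ours.b - b) < 0.05

    def test_collinear_points_fail(self):
        pts = np.stack([np.arange(10.0), 2 * np.arange(10.0)], axis=1)
        with pytest.raises(GeometryError):
            fit_ellipse(pts)


class TestTangents:
    CIRCLE = Ellipse(center=(10, 0), a=5, b=5, angle_deg=0)

    def test_circle_closed_form(self):
        p1, p2 = tangent_points(self.CIRCLE, (0, 0))
        ys = sorted([p1[1], p2[1]])
        assert np.allclose([p1[0], p2[0]], 7.5, atol=1e-9)
        assert np.allclose(ys, [-np.sqrt(18.75), np.sqrt(18.75)], atol=1e-9)

    def test_point_inside_rejected(self):
        with pytest.raises(GeometryError):
            tangent_points(self.CIRCLE, (10, 1))

    def test_axis_point_symmetry(self):
        e = Ellipse(center=(0, 0), a=4, b=2, angle_deg=0)
        p1, p2 = tangent_points(e, (10, 0))
        assert abs(p1[0] - p2[0]) < 1e-9
        assert abs(p1[1] + p2[1]) < 1e-9

    def test_tangency_discriminant_random_fixtures(self, rng):
        """Each tangent line meets the conic with multiplicity 2."""
        for _ in range(200):
            e = Ellipse(center=tuple(rng.uniform(-20, 20, 2)),
                        a=(ab := sorted(rng.uniform(1, 10, 2)))[1], b=ab[0],
                        angle_deg=rng.uniform(0, 180))
            p = tuple(e.center + rng.uniform(1.5, 4) * e.a *
                      np.array([np.cos(t := rng.uniform(0, 2 * np.pi)), np.sin(t)]))
            for tp in tangent_points(e, p):
                assert _line_conic_discriminant(e, p, tp) < 1e-6

    def test_selection_max_angle_and_tie_break(self):
        cands = tangent_points(self.CIRCLE, (0, 0))
        sel = select_tangent(cands, (-10, 0), (0, 0))
        assert sel[1] > 0  # tie at 150 deg -> larger y wins
        # an asymmetric left endpoint breaks the tie toward the larger angle
        sel2 = select_tangent(cands, (-10, 3), (0, 0))
        a1 = compute_aop((-10, 3), (0, 0), cands[0])
        a2 = compute_aop((-10, 3), (0, 0), cands[1])
        assert compute_aop((-10, 3), (0, 0), sel2) == max(a1, a2)

    def test_selection_rotation_invariant(self, rng):
        e = Ellipse(center=(12, 3), a=5, b=3, angle_deg=20)
        left, right = (-8.0, 1.0), (2.0, 2.0)
        base = measureless_aop(e, left, right)
        for _ in range(20):
            th = rng.uniform(0, 2 * np.pi)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            er = Ellipse(center=tuple(R @ e.center), a=e.a, b=e.b,
                         angle_deg=e.angle_deg + np.degrees(th))
            aop = measureless_aop(er, tuple(R @ left), tuple(R @ right))
            assert abs(aop - base) < 1e-6


def measureless_aop(e, left, right):
    cands = tangent_points(e, right)
    return compute_aop(left, right, select_tangent(cands, left, right))


def _line_conic_discriminant(e, p, q):
    """Normalized discriminant of the conic restricted to line p-q."""
    Q = e.conic_matrix
    p = np.array([p[0], p[1], 1.0])
    d = np.array([q[0] - p[0], q[1] - p[1], 0.0])
    d[:2] /= np.linalg.norm(d[:2])
    qa, qb, qc = d @ Q @ d, 2 * (d @ Q @ p), p @ Q @ p
    return abs(qb * qb - 4 * qa * qc) / max(abs(qa), 1e-12)


class TestComputeAoP:
    @pytest.mark.parametrize("tangent,expected", [
        ((10, 10), 90.0), ((20, 0), 180.0)])
    def test_simple_angles(self, tangent, expected):
        assert abs(compute_aop((0, 0), (10, 0), tangent) - expected) < 1e-12

    def test_circle_fixture_150(self):
        aop = measureless_aop(TestTangents.CIRCLE, (-10, 0), (0, 0))
        assert abs(aop - 150.0) < 1e-9
        assert abs(aop - (180 - np.degrees(np.arcsin(5 / 10)))) < 1e-9

    def test_coincident_points_rejected(self):
        with pytest.raises(GeometryError):
            compute_aop((0, 0), (0, 0), (1, 1))

    def test_scale_invariance(self):
        pts = [(-10, 2), (0, 0), (7, 6)]
        base = compute_aop(*pts)
        scaled = compute_aop(*[(37.5 * x, 37.5 * y) for x, y in pts])
        assert abs(base - scaled) < 1e-9


class TestMaskBoundary:
    def test_rectangle_corners_on_boundary(self):
        m = np.zeros((20, 30), np.uint8)
        m[5:15, 8:25] = 2
        pts = mask_boundary(m, 2)
        for corner in [(8, 5), (24, 5), (8, 14), (24, 14)]:
            assert np.min(np.hypot(pts[:, 0] - corner[0], pts[:, 1] - corner[1])) < 1.0

    def test_largest_component_rule(self):
        m = np.zeros((40, 40), np.uint8)
        m[2:6, 2:6] = 2          # small blob
        m[10:35, 10:35] = 2      # large blob
        pts = mask_boundary(m, 2)
        assert pts[:, 0].min() > 8  # boundary comes from the large blob only

    def test_disk_boundary_within_one_pixel(self):
        yy, xx = np.mgrid[0:64, 0:64]
        m = (((xx - 32) ** 2 + (yy - 32) ** 2) <= 20**2).astype(np.uint8) * 2
        pts = mask_boundary(m, 2)
        r = np.hypot(pts[:, 0] - 32, pts[:, 1] - 32)
        assert np.abs(r - 20).max() < 1.0

    def test_too_few_pixels(self):
        m = np.zeros((10, 10), np.uint8)
        m[3, 3] = 2
        with pytest.raises(GeometryError):
            mask_boundary(m, 2)


class TestMeasure:
    def test_phantom_oracle(self, desk_spec):
        errs = []
        for i in range(100):
            s = phantom.generate_standard(desk_spec, "P0", 5000 + i)
            r = measure(s.mask, (s.left_endpoint, s.right_endpoint))
            assert r.valid, r.reason
            errs.append(abs(r.aop_deg - s.aop_true))
        assert np.mean(errs) < 1.0

    def test_endpoint_inside_fails(self, standard_sample):
        s = standard_sample
        inside = s.fh_ellipse.center
        r = measure(s.mask, (s.left_endpoint, inside))
        assert not r.valid and "tangent" in r.reason

    def test_no_fh_region_fails(self, standard_sample):
        mask = np.where(standard_sample.mask == 2, 0, standard_sample.mask)
        r = measure(mask, (standard_sample.left_endpoint,
                           standard_sample.right_endpoint))
        assert not r.valid and "FH" in r.reason

    def test_rigid_motion_tolerance(self, standard_sample):
        from scipy import ndimage
        s = standard_sample
        base = measure(s.mask, (s.left_endpoint, s.right_endpoint))
        # 90-degree rotation is exact on the grid
        rot = np.rot90(s.mask, k=-1)  # (x, y) -> (H-1-y, x) in xy coords
        h = s.mask.shape[0]
        def rot_pt(p):
            return (h - 1 - p[1], p[0])
        r = measure(rot, (rot_pt(s.left_endpoint), rot_pt(s.right_endpoint)))
        assert r.valid
        assert abs(r.aop_deg - base.aop_deg) < 0.5
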