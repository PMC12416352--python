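"""Shape metrics: construct-and-recover on analytic torus geometries."""
import math

import numpy as np
import pytest

from eulfsi.grid import CartesianGrid, VectorField
from eulfsi.shape import (Isosurface, bending_angles, centroid,
                          centroid_velocity, cross_section_ellipses,
                          fit_ellipse, isosurface, local_frame,
                          moving_average, orientation,
                          projected_circle_ratios, spectrum)


def torus_points(r=0.1, R=0.3, psi_deg=0.0, n_u=60, n_v=40, center=(0, 0, 0),
                 squash_x=1.0, scale=1.0, bend=0.0):
    """Analytic torus surface point cloud.

    The axis n = (cos psi, sin psi, 0).  ``squash_x`` compresses the tube
    along the local flow-ish direction, ``bend`` displaces the ring along
    the axis proportional to |angle| (a simple bent-ring model).
    """
    u = np.linspace(0, 2 * np.pi, n_u, endpoint=False)
    v = np.linspace(0, 2 * np.pi, n_v, endpoint=False)
    U, V = np.meshgrid(u, v, indexing="ij")
    # local frame: z' = axis; ring in (x', y') plane
    rho = R + r * np.cos(V)
    xl = rho * np.cos(U)
    yl = rho * np.sin(U)
    zl = r * np.sin(V) + bend * np.abs(np.sin(U)) * R
    psi = math.radians(psi_deg)
    n = np.array([math.cos(psi), math.sin(psi), 0.0])
    e1 = np.array([0.0, 0.0, 1.0])             # local x' = global z
    e2 = np.cross(n, e1)
    pts = (np.outer(xl.ravel(), e1) + np.outer(yl.ravel(), e2)
           + np.outer(zl.ravel(), n))
    pts *= scale
    # squash along global x
    pts[:, 0] *= squash_x
    return pts + np.asarray(center)


def torus_mesh(**kw):
    """Triangulated analytic torus (periodic grid connectivity)."""
    n_u = kw.pop("n_u", 80)
    n_v = kw.pop("n_v", 40)
    pts = torus_points(n_u=n_u, n_v=n_v, **kw)
    faces = []
    for i in range(n_u):
        for j in range(n_v):
            a = i * n_v + j
            b = ((i + 1) % n_u) * n_v + j
            c = i * n_v + (j + 1) % n_v
            d = ((i + 1) % n_u) * n_v + (j + 1) % n_v
            faces.append((a, b, c))
            faces.append((b, d, c))
    return Isosurface(pts, np.array(faces))


class TestCentroid:
    def test_symmetric_field(self):
        g = CartesianGrid((16, 16), (1, 1))
        a = np.zeros(g.shape3)
        a[4:12, 4:12] = 1.0
        assert np.allclose(centroid(a, g)[:2], [0.5, 0.5], atol=1e-12)

    def test_two_cell_weighted_mean(self):
        """alpha = {1, 0.5} at positions {0, 1} (cell units) -> 1/3."""
        g = CartesianGrid((2, 1, 1), (2, 1, 1))
        a = np.zeros(g.shape3)
        a[0] = 1.0
        a[1] = 0.5
        xc = centroid(a, g)
        # cell centers at 0.5 and 1.5: weighted mean = (0.5 + 0.75)/1.5
        assert xc[0] == pytest.approx((0.5 * 1 + 1.5 * 0.5) / 1.5)

    def test_empty_solid_raises(self):
        g = CartesianGrid((4, 4), (1, 1))
        with pytest.raises(ValueError):
            centroid(np.zeros(g.shape3), g)

    def test_periodic_seam_unwrap(self):
        g = CartesianGrid((32, 8, 8), (4, 1, 1), periodic=(True, False,
                                                           False))
        a = np.zeros(g.shape3)
        a[30:, 2:6, 2:6] = 1.0
        a[:2, 2:6, 2:6] = 1.0
        xc = centroid(a, g)
        assert xc[0] == pytest.approx(0.0, abs=1e-9) or \
            xc[0] == pytest.approx(4.0, abs=1e-9)

    def test_rigid_translation_velocity(self):
        g = CartesianGrid((16, 16), (1, 1), periodic=(True, True))
        a = np.zeros(g.shape3)
        a[4:8, 4:8] = 1.0
        u = VectorField(g)
        u.comps[0][:] = 0.7
        u.comps[1][:] = -0.2
        uc = centroid_velocity(a, u, g)
        assert np.allclose(uc[:2], [0.7, -0.2], atol=1e-12)


class TestOrientation:
    def test_ring_in_yz_plane_has_psi_zero(self):
        th = np.linspace(0, 2 * np.pi, 300, endpoint=False)
        pts = np.stack([np.zeros_like(th), 0.3 * np.cos(th),
                        0.3 * np.sin(th)], axis=1)
        n, psi, degen = orientation(pts, np.zeros(3))
        assert not degen
        assert abs(n[0]) == pytest.approx(1.0, abs=1e-9)
        assert psi == pytest.approx(0.0, abs=1e-6)

    def test_rotated_torus_angle_recovered(self):
        pts = torus_points(psi_deg=45.0, n_u=80, n_v=50)
        n, psi, _ = orientation(pts, pts.mean(axis=0))
        assert psi == pytest.approx(45.0, abs=0.5)

    def test_sphere_cloud_flags_degenerate(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((500, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        prev = np.array([1.0, 0.0, 0.0])
        n, psi, degen = orientation(v, np.zeros(3), prev_n=prev,
                                    gap_tol=1e-2)
        assert degen
        assert np.allclose(n, prev)

    def test_orientation_invariant_under_translation(self):
        pts = torus_points(psi_deg=30.0)
        _, psi1, _ = orientation(pts, pts.mean(axis=0))
        shift = np.array([1.7, -2.2, 0.4])
        _, psi2, _ = orientation(pts + shift, pts.mean(axis=0) + shift)
        assert psi1 == pytest.approx(psi2, abs=1e-9)

    def test_psi_invariant_under_rotation_about_x(self):
        pts = torus_points(psi_deg=30.0)
        th = 0.7
        Rx = np.array([[1, 0, 0],
                       [0, np.cos(th), -np.sin(th)],
                       [0, np.sin(th), np.cos(th)]])
        _, psi1, _ = orientation(pts, pts.mean(axis=0))
        _, psi2, _ = orientation(pts @ Rx.T, (pts @ Rx.T).mean(axis=0))
        assert psi1 == pytest.approx(psi2, abs=1e-6)


class TestLocalFrame:
    def test_frame_for_x_axis(self):
        f = local_frame([1.0, 0.0, 0.0])
        assert np.allclose(f.zeta, [0, 0, 1])
        assert np.allclose(f.xi, [1, 0, 0])
        f.check()

    def test_zeta_unchanged_when_already_orthogonal(self):
        n = np.array([np.cos(0.7), np.sin(0.7), 0.0])
        f = local_frame(n)
        assert np.allclose(f.zeta, [0, 0, 1], atol=1e-12)

    def test_orthonormal_for_generic_n(self):
        f = local_frame([0.5, 0.3, 0.4])
        f.check(tol=1e-12)

    def test_parallel_to_z_rejected(self):
        with pytest.raises(ValueError):
            local_frame([0.0, 0.0, 1.0])


class TestEllipseFit:
    def test_exact_ellipse_recovered(self):
        th = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        h, w, ang = 2.0, 1.0, math.radians(30)
        X0, Y0 = 0.3, -0.2
        A = h * np.cos(th)
        B = w * np.sin(th)
        X = X0 + A * np.cos(ang) - B * np.sin(ang)
        Y = Y0 + A * np.sin(ang) + B * np.cos(ang)
        fit = fit_ellipse(X, Y)
        assert fit.rms < 1e-10
        assert sorted([fit.h, fit.w]) == pytest.approx([1.0, 2.0], abs=1e-6)
        assert fit.center[0] == pytest.approx(X0, abs=1e-6)
        assert fit.aspect_ratio == pytest.approx(0.5, abs=1e-6)


class TestCrossSections:
    def test_undeformed_torus_all_ratios_one(self):
        surf = torus_mesh(psi_deg=45.0)
        xc = surf.verts.mean(axis=0)
        n, _, _ = orientation(surf, xc)
        frame = local_frame(n)
        ell = cross_section_ellipses(surf, frame, xc)
        for name in ("forward", "back", "right", "left"):
            assert ell[name] is not None, name
            assert ell[name].aspect_ratio == pytest.approx(1.0, abs=0.02)

    def test_squashed_tube_ratio_recovered(self):
        """Tube cross-sections squashed 2:1 along the flow: the fitted
        aspect ratios drop to ~0.5."""
        surf = torus_mesh(psi_deg=0.0, squash_x=0.5)
        xc = surf.verts.mean(axis=0)
        frame = local_frame([1.0, 0.0, 0.0])
        ell = cross_section_ellipses(surf, frame, xc)
        for name in ("forward", "back", "right", "left"):
            assert ell[name].aspect_ratio == pytest.approx(0.5, abs=0.03)

    def test_few_points_reported_missing(self):
        surf = torus_mesh(psi_deg=45.0, n_u=12, n_v=6)
        xc = surf.verts.mean(axis=0)
        frame = local_frame([1.0, 0.0, 0.0])
        ell = cross_section_ellipses(surf, frame, xc, min_points=10_000)
        assert all(v is None for v in ell.values())

    def test_ratios_scale_invariant(self):
        s1 = torus_mesh(psi_deg=30.0, squash_x=0.7)
        s2 = torus_mesh(psi_deg=30.0, squash_x=0.7, scale=2.0)
        for s in (s1, s2):
            pass
        def ratios(surf):
            xc = surf.verts.mean(axis=0)
            n, _, _ = orientation(surf, xc)
            frame = local_frame(n)
            ell = cross_section_ellipses(surf, frame, xc)
            return [ell[k].aspect_ratio for k in ("forward", "back")]
        assert ratios(s1) == pytest.approx(ratios(s2), abs=1e-3)


class TestBending:
    def _frame(self):
        return local_frame([1.0, 0.0, 0.0])

    def test_collinear_centers_zero_angle(self):
        from eulfsi.shape import EllipseFit
        f = self._frame()
        xc = np.zeros(3)
        e = {}
        for name, c in (("forward", [0, 0.3, 0]), ("back", [0, -0.3, 0])):
            fit = EllipseFit(np.zeros(2), 1, 1, 0, 0)
            fit.center3 = np.array(c, float)
            e[name] = fit
        bm, bp = bending_angles(e, xc, f)
        assert bm == pytest.approx(0.0, abs=1e-9)

    def test_known_displacement_angle_and_sign(self):
        """Centers displaced +0.1 along xi with arms 0.3:
        angle = 2 atan(0.1/0.3) ~ 36.87 deg, positive."""
        from eulfsi.shape import EllipseFit
        f = self._frame()
        xc = np.zeros(3)
        xi = f.xi
        eta = f.eta
        e = {}
        for name, s in (("forward", 1.0), ("back", -1.0)):
            fit = EllipseFit(np.zeros(2), 1, 1, 0, 0)
            fit.center3 = s * 0.3 * eta + 0.1 * xi
            e[name] = fit
        bm, _ = bending_angles(e, xc, f)
        expect = 2 * math.degrees(math.atan(0.1 / 0.3))
        assert bm == pytest.approx(expect, abs=1e-9)
        # mirror displacement flips the sign only
        for name, s in (("forward", 1.0), ("back", -1.0)):
            e[name].center3 = s * 0.3 * eta - 0.1 * xi
        bm2, _ = bending_angles(e, xc, f)
        assert bm2 == pytest.approx(-expect, abs=1e-9)

    def test_bent_torus_mesh_angle_recovered(self):
        surf = torus_mesh(psi_deg=0.0, bend=0.15)
        xc = surf.verts.mean(axis=0)
        frame = local_frame([1.0, 0.0, 0.0])
        ell = cross_section_ellipses(surf, frame, xc)
        bm, bp = bending_angles(ell, xc, frame)
        assert bm is not None and bm > 5.0   # bent toward +xi


class TestProjectedCircles:
    def test_undeformed_torus_ratios_one(self):
        surf = torus_mesh(psi_deg=0.0)
        xc = surf.verts.mean(axis=0)
        frame = local_frame([1.0, 0.0, 0.0])
        inner, outer = projected_circle_ratios(surf, frame, xc)
        assert inner == pytest.approx(1.0, abs=0.02)
        assert outer == pytest.approx(1.0, abs=0.02)

    def test_stretched_torus_ratio(self):
        """Scaling x1.5 along eta drops both ratios to ~1/1.5."""
        surf = torus_mesh(psi_deg=0.0, n_u=240, n_v=40)
        frame = local_frame([1.0, 0.0, 0.0])
        v = surf.verts.copy()
        amp = v @ frame.eta
        v = v + 0.5 * amp[:, None] * frame.eta[None, :]
        surf2 = Isosurface(v, surf.faces)
        xc = v.mean(axis=0)
        inner, outer = projected_circle_ratios(surf2, frame, xc)
        assert inner == pytest.approx(1 / 1.5, abs=0.03)
        assert outer == pytest.approx(1 / 1.5, abs=0.03)

    def test_sphere_has_no_inner_outline(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((4000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        surf = Isosurface(v, np.zeros((0, 3), dtype=int))
        frame = local_frame([1.0, 0.0, 0.0])
        inner, outer = projected_circle_ratios(surf, frame, np.zeros(3))
        assert inner is None
        assert outer == pytest.approx(1.0, abs=0.05)


class TestSeriesUtils:
    def test_moving_average_constant_unchanged(self):
        s = np.full(10, 3.3)
        assert np.allclose(moving_average(s, 5), 3.3)

    def test_moving_average_edge_truncation(self):
        out = moving_average([0, 3, 0, 3, 0], 3)
        assert np.allclose(out, [1.5, 1, 2, 1, 1.5])

    def test_moving_average_window_validation(self):
        with pytest.raises(ValueError):
            moving_average([1, 2], 0)

    def test_spectrum_peak_at_input_frequency(self):
        dt = 0.01
        t = np.arange(512) * dt
        f0 = 5.0
        freq, amp = spectrum(np.sin(2 * np.pi * f0 * t) + 2.0, dt)
        assert freq[np.argmax(amp)] == pytest.approx(f0, abs=freq[1])


class TestMarchingCubesExtraction:
    def test_torus_isosurface_topology(self):
        from eulfsi.particles import ParticleSpec, rasterize
        g = CartesianGrid((48, 48, 48), (1, 1, 1))
        sp = ParticleSpec("torus", {"r": 0.1, "R": 0.3}, (0.5, 0.5, 0.5))
        surf = isosurface(rasterize(sp, g))
        assert surf.euler_characteristic() == 0
        sp2 = ParticleSpec("sphere", {"r": 0.25}, (0.5, 0.5, 0.5))
        surf2 = isosurface(rasterize(sp2, g))
        assert surf2.euler_characteristic() == 2
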