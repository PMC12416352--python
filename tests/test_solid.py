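"""Corrected left Cauchy-Green tensor: evolution, clipping, elastic force."""
import numpy as np
import pytest

from eulfsi.grid import CartesianGrid, SymTensorField, VectorField
from eulfsi.solid import (BlowUpError, SolidProps, btilde_initial,
                          clip_btilde, elastic_force, evolve_btilde)


def _shear_velocity(grid, gamma):
    u = VectorField(grid)
    yc = (np.arange(grid.shape3[1]) + 0.5) * grid.dx
    u.comps[0][:] = gamma * yc[None, :, None]
    return u


class TestProps:
    def test_beta_must_be_half(self):
        with pytest.raises(ValueError):
            SolidProps(G=1.0, mu_s=0.0, beta=0.3)
        SolidProps(G=1.0, mu_s=0.0, beta=0.3, allow_beta_override=True)

    def test_alpha_min_range(self):
        with pytest.raises(ValueError):
            SolidProps(G=1.0, mu_s=0.0, alpha_min=0.6)


class TestEvolution:
    def test_uniform_field_in_uniform_flow_is_unchanged(self):
        g = CartesianGrid((16, 16), (1, 1), periodic=(True, True))
        u = VectorField(g)
        u.comps[0][:] = 0.7
        u.comps[1][:] = -0.3
        B = SymTensorField.identity(g, scale=2.5)
        B.data[3] = 0.4
        B2 = evolve_btilde(B, u, 5e-3)
        assert np.allclose(B2.data, B.data, atol=1e-13)

    def test_simple_shear_closed_form(self):
        """Full solid, u = (gamma y, 0): B_xx = 1+(gamma t)^2,
        B_xy = gamma t, B_yy = 1.  The trapezoidal step integrates this
        quadratic-in-time solution exactly."""
        gamma = 1.0
        N = 16
        g = CartesianGrid((N, N), (1, 1))   # one-sided L exact for linear u
        u = _shear_velocity(g, gamma)
        errs = []
        for nsteps in (25, 50):
            B = SymTensorField.identity(g)
            dt = 0.5 / nsteps
            for _ in range(nsteps):
                B = evolve_btilde(B, u, dt)
            t = 0.5
            errs.append(max(
                np.abs(B.comp("xx") - (1 + (gamma * t) ** 2)).max(),
                np.abs(B.comp("xy") - gamma * t).max(),
                np.abs(B.comp("yy") - 1.0).max()))
        # exact up to round-off; comfortably beats the O(dt^2) contract
        assert errs[0] < 1e-12 and errs[1] < 1e-12

    def test_temporal_order_on_rotating_shear(self):
        """Observed order >= 1.8 on a problem whose solution is not
        polynomial in time (rotation + stretch)."""
        N = 16
        g = CartesianGrid((N, N), (1, 1))
        u = VectorField(g)
        yc = (np.arange(N) + 0.5) * g.dx
        xc = (np.arange(N) + 0.5) * g.dx
        u.comps[0][:] = (0.5 * yc)[None, :, None]
        u.comps[1][:] = (0.8 * xc)[:, None, None]
        # L = [[0, .5], [.8, 0]] constant: B(t) = exp(tL) exp(tL)^T
        import scipy.linalg as sla
        L = np.array([[0.0, 0.5, 0.0], [0.8, 0.0, 0.0], [0.0, 0.0, 0.0]])
        T = 0.4

        def exact(t):
            F = sla.expm(t * L)
            return F @ F.T

        Bex = exact(T)
        errs = []
        for nsteps in (16, 32):
            B = SymTensorField.identity(g)
            dt = T / nsteps
            for _ in range(nsteps):
                B = evolve_btilde(B, u, dt)
            # the field stays spatially uniform up to advection noise at
            # the replicated edges; probe the center cell
            c = N // 2
            got = np.array([[B.comp("xx")[c, c, 0], B.comp("xy")[c, c, 0]],
                            [B.comp("xy")[c, c, 0], B.comp("yy")[c, c, 0]]])
            errs.append(np.abs(got - Bex[:2, :2]).max())
        order = np.log2(errs[0] / errs[1])
        assert order >= 1.8

    def test_rigid_rotation_preserves_identity(self):
        N = 16
        g = CartesianGrid((N, N), (1, 1))
        u = VectorField(g)
        yc = (np.arange(N) + 0.5) * g.dx
        xc = (np.arange(N) + 0.5) * g.dx
        u.comps[0][:] = (-(yc - 0.5))[None, :, None]
        u.comps[1][:] = (xc - 0.5)[:, None, None]
        B = SymTensorField.identity(g)
        for _ in range(50):
            B = evolve_btilde(B, u, 1e-2)
        assert np.abs(B.comp("xx") - 1).max() < 1e-12
        assert np.abs(B.comp("xy")).max() < 1e-12

    def test_symmetry_is_preserved_by_storage(self):
        g = CartesianGrid((8, 8), (1, 1), periodic=(True, True))
        rng = np.random.default_rng(0)
        u = VectorField(g)
        for c in u.comps:
            c += 0.1 * rng.standard_normal(c.shape)
        u.sync_periodic()
        B = SymTensorField.identity(g)
        B2 = evolve_btilde(B, u, 1e-3)
        # six-component storage: B - B^T == 0 identically
        assert B2.data.shape[0] == 6

    def test_objectivity_rigid_rotation_of_stressed_state(self):
        """A uniformly pre-stressed full solid under rigid rotation follows
        B(t) = R B0 R^T (checked at a quarter turn within O(dx^2))."""
        N = 32
        g = CartesianGrid((N, N), (1, 1))
        u = VectorField(g)
        yc = (np.arange(N) + 0.5) * g.dx
        xc = (np.arange(N) + 0.5) * g.dx
        om = 1.0
        u.comps[0][:] = (-om * (yc - 0.5))[None, :, None]
        u.comps[1][:] = (om * (xc - 0.5))[:, None, None]
        B = SymTensorField.identity(g)
        B.data[3] = 0.3     # uniform shear pre-stress
        T = np.pi / 2 / om  # quarter revolution
        nst = 400
        dt = T / nst
        for _ in range(nst):
            B = evolve_btilde(B, u, dt)
        th = om * T
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        B0 = np.array([[1.0, 0.3], [0.3, 1.0]])
        Bex = R @ B0 @ R.T
        c = N // 2
        got = np.array([[B.comp("xx")[c, c, 0], B.comp("xy")[c, c, 0]],
                        [B.comp("xy")[c, c, 0], B.comp("yy")[c, c, 0]]])
        assert np.abs(got - Bex).max() < 10.0 * g.dx ** 2 + 5e-3

    def test_blow_up_raises(self):
        g = CartesianGrid((8, 8), (1, 1), periodic=(True, True))
        u = VectorField(g)
        B = SymTensorField.identity(g, scale=1e7)
        with pytest.raises(BlowUpError):
            evolve_btilde(B, u, 1e-3)


class TestClip:
    def setup_method(self):
        self.g = CartesianGrid((4, 4), (1, 1))
        self.props_zero = SolidProps(G=1.0, mu_s=0.0, reset="zero")
        self.props_unit = SolidProps(G=1.0, mu_s=0.0, reset="unit")

    def test_below_threshold_resets_zero_mode(self):
        a = np.full(self.g.shape3, 0.05)
        B = SymTensorField.identity(self.g, scale=2.0)
        clip_btilde(B, a, self.props_zero, clip_alpha=True)
        assert np.all(B.data == 0.0)
        assert np.all(a == 0.0)

    def test_below_threshold_resets_unit_mode(self):
        a = np.full(self.g.shape3, 0.05)
        B = SymTensorField.identity(self.g, scale=2.0)
        B.data[3] = 0.7
        clip_btilde(B, a, self.props_unit, clip_alpha=False)
        assert np.all(B.data[0] == 1.0) and np.all(B.data[3] == 0.0)
        assert np.all(a == 0.05)   # mass preserved in this mode

    def test_above_threshold_untouched(self):
        a = np.full(self.g.shape3, 0.5)
        B = SymTensorField.identity(self.g, scale=2.0)
        clip_btilde(B, a, self.props_zero)
        assert np.all(B.data[0] == 2.0)

    def test_exactly_at_threshold_untouched(self):
        """Strict inequality at alpha == alpha_min."""
        a = np.full(self.g.shape3, 0.1)
        B = SymTensorField.identity(self.g, scale=2.0)
        clip_btilde(B, a, self.props_zero)
        assert np.all(B.data[0] == 2.0)
        assert np.all(a == 0.1)


class TestElasticForce:
    def test_undeformed_solid_exerts_no_force(self):
        g = CartesianGrid((16, 16), (1, 1), periodic=(True, True))
        props = SolidProps(G=3.0, mu_s=0.0, reset="zero")
        alpha = np.full(g.shape3, 0.6)
        B = btilde_initial(g, alpha, props)   # alpha^(1/2) I
        f = elastic_force(B, alpha, props)
        assert max(np.abs(c).max() for c in f) < 1e-13

    def test_linear_shear_state_gives_uniform_force(self):
        """alpha = 1, B~_xy = gamma x  ->  force_y = G gamma."""
        G = 2.0
        gamma = 1.5
        g = CartesianGrid((16, 16), (1, 1))
        props = SolidProps(G=G, mu_s=0.0, reset="unit")
        alpha = np.ones(g.shape3)
        B = SymTensorField.identity(g)
        B.data[3] = gamma * g.cell_centers()[0]
        f = elastic_force(B, alpha, props)
        interior = f[1][2:-2, 2:-2, :]
        assert np.allclose(interior, G * gamma, atol=1e-10)

    def test_zero_alpha_gives_zero_field(self):
        g = CartesianGrid((8, 8), (1, 1))
        props = SolidProps(G=5.0, mu_s=0.0)
        B = SymTensorField.identity(g, scale=3.0)
        B.data[3] = 1.0
        f = elastic_force(B, np.zeros(g.shape3), props)
        assert max(np.abs(c).max() for c in f) == 0.0
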