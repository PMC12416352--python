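"""Momentum solver: time-step rule, projection, forcing controller,
Q-criterion, conservation properties."""
import numpy as np
import pytest

from eulfsi.axisym import AxisymmetricPipeFlow
from eulfsi.flow import (FlowState, MomentumSolver, StagnationError,
                         compute_dt, mean_flow_forcing, q_criterion)
from eulfsi.grid import CartesianGrid, ScalarField, VectorField
from eulfsi.operators import divergence

from conftest import solenoidal_velocity


class TestComputeDt:
    def _state(self, g, umax):
        u = VectorField(g)
        u.comps[0][:] = umax
        return FlowState(u=u, p_rgh=ScalarField(g))

    def test_cfl_limited(self):
        g = CartesianGrid((64, 64), (1, 1))
        st = self._state(g, 1.0)
        dt = compute_dt(st, g, co=0.1, nu_max=1e-4, G=0.01)
        assert dt == pytest.approx(0.1 / 64)

    def test_viscous_limited(self):
        g = CartesianGrid((64, 64), (1, 1))
        st = self._state(g, 1.0)
        nu = 10.0
        dt = compute_dt(st, g, co=0.1, nu_max=nu, G=0.0)
        assert dt == pytest.approx(g.dx ** 2 / (3 * nu))

    def test_elastic_wave_bound_combines_with_cfl(self):
        g = CartesianGrid((64, 64), (1, 1))
        st = self._state(g, 0.01)
        dt = compute_dt(st, g, co=0.1, nu_max=0.0, G=1.0)
        # Co bound 0.1*dx/0.01 = 0.15625; elastic bound dx = 1/64 binds
        assert dt == pytest.approx(1.0 / 64)

    def test_stagnation_error(self):
        g = CartesianGrid((8, 8), (1, 1))
        st = self._state(g, 1e12)
        with pytest.raises(StagnationError):
            compute_dt(st, g, co=0.1, nu_max=0.0, G=0.0, floor=1e-10)


class TestQCriterion:
    def test_pure_shear_is_zero(self):
        g = CartesianGrid((16, 16), (1, 1))
        u = VectorField(g)
        yc = (np.arange(16) + 0.5) * g.dx
        u.comps[0][:] = yc[None, :, None]
        q = q_criterion(u).data
        assert np.abs(q[1:-1, 1:-1]).max() < 1e-12

    def test_rigid_rotation_is_one(self):
        g = CartesianGrid((16, 16), (1, 1))
        u = VectorField(g)
        yc = (np.arange(16) + 0.5) * g.dx
        xc = (np.arange(16) + 0.5) * g.dx
        u.comps[0][:] = (-(yc - 0.5))[None, :, None]
        u.comps[1][:] = (xc - 0.5)[:, None, None]
        q = q_criterion(u).data
        assert np.allclose(q[1:-1, 1:-1], 1.0, atol=1e-10)

    def test_uniform_flow_is_zero(self):
        g = CartesianGrid((8, 8), (1, 1), periodic=(True, True))
        u = VectorField(g)
        u.comps[0][:] = 2.0
        assert np.abs(q_criterion(u).data).max() < 1e-13


class TestProjection:
    def test_rest_state_stays_at_rest(self):
        g = CartesianGrid((16, 16), (1, 1))
        bc = {(a, s): ("wall", (0.0, 0.0, 0.0))
              for a in (0, 1) for s in (0, 1)}
        ms = MomentumSolver(g, nu_f=0.01, nu_s=0.01, vel_bc=bc)
        fl = FlowState(u=VectorField(g), p_rgh=ScalarField(g))
        for _ in range(5):
            fl = ms.momentum_step(fl, None, None, None, 1e-3)
        assert fl.max_speed() == 0.0

    def test_projection_removes_divergence(self):
        g = CartesianGrid((32, 32), (1, 1), periodic=(True, True))
        ms = MomentumSolver(g, nu_f=0.01, nu_s=0.01)
        rng = np.random.default_rng(7)
        u = VectorField(g)
        for c in u.comps:
            c += 0.3 * rng.standard_normal(c.shape)
        u.sync_periodic()
        fl = FlowState(u=u, p_rgh=ScalarField(g))
        fl = ms.momentum_step(fl, None, None, None, 1e-3)
        assert fl.poisson_residual < 1e-8

    def test_kinetic_energy_decays_without_forcing(self):
        g = CartesianGrid((32, 32), (1, 1), periodic=(True, True))
        ms = MomentumSolver(g, nu_f=0.01, nu_s=0.01)
        u = solenoidal_velocity(g, seed=2)
        fl = FlowState(u=u, p_rgh=ScalarField(g))

        def ke(u):
            tot = 0.0
            for a, c in enumerate(u.comps):
                cc = np.moveaxis(c, a, 0)[:-1]
                tot += float(np.sum(cc ** 2))
            return tot

        k = ke(fl.u)
        for _ in range(20):
            fl = ms.momentum_step(fl, None, None, None, 1e-3)
            k2 = ke(fl.u)
            assert k2 <= k * (1 + 1e-12)
            k = k2

    def test_momentum_conserved_on_periodic_box(self):
        """Action/reaction: with S = 0 the total momentum change per step is
        round-off (conservative fluxes)."""
        g = CartesianGrid((32, 32), (1, 1), periodic=(True, True))
        ms = MomentumSolver(g, nu_f=0.01, nu_s=0.01)
        u = solenoidal_velocity(g, seed=4)
        fl = FlowState(u=u, p_rgh=ScalarField(g))

        def mom(u):
            out = []
            for a, c in enumerate(u.comps):
                out.append(float(np.sum(np.moveaxis(c, a, 0)[:-1])))
            return np.array(out)

        m0 = mom(fl.u)
        for _ in range(20):
            fl = ms.momentum_step(fl, None, None, None, 2e-3)
        assert np.abs(mom(fl.u) - m0).max() < 1e-10


class TestForcingController:
    def test_zero_correction_at_target(self):
        g = CartesianGrid((16, 8, 8), (2, 1, 1),
                          periodic=(True, False, False))
        ms = MomentumSolver(g, nu_f=0.01, nu_s=0.01)
        u = VectorField(g)
        u.comps[0][:] = 0.5
        fl = FlowState(u=u, p_rgh=ScalarField(g))
        fl, mean = mean_flow_forcing(fl, ms, 0.5, 1e-3)
        assert mean == pytest.approx(0.5)
        assert fl.S == pytest.approx(0.0, abs=1e-12)

    def test_reaches_target_from_rest_and_holds(self):
        """Bulk velocity within 1% of target after O(10) steps, then within
        0.1% (axisymmetric reduction)."""
        f = AxisymmetricPipeFlow(n_radial=32)
        dt = f.nominal_dt()
        for _ in range(10):
            f.advance(dt)
        assert abs(f.bulk_velocity() - 0.5) < 0.005
        for _ in range(100):
            f.advance(dt)
        assert abs(f.bulk_velocity() - 0.5) < 5e-4

    def test_steady_forcing_matches_poiseuille_gradient(self):
        """S -> 16/Re_U: the analytic pressure-gradient balance."""
        f = AxisymmetricPipeFlow(n_radial=32)
        res = f.run_to_steady(tol=1e-9)
        assert res.S == pytest.approx(f.analytic_forcing, rel=1e-5)


def test_poiseuille_profile_injected_gives_zero_l2():
    from eulfsi.axisym import l2_error, poiseuille_profile
    y = np.linspace(0.01, 0.99, 64)
    assert l2_error(poiseuille_profile(y), poiseuille_profile(y)) == 0.0
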