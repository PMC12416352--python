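"""One-field momentum equation: explicit predictor, incremental pressure
projection, adaptive time step and the mean-flow forcing controller.

Both phases share a single velocity field; the solid enters through the
mixture viscosity and the elastic force (G/rho) div(alpha^(1/2) dev B~).
Because the grid is staggered, the projection uses the exact discrete
adjoint divergence/gradient pair and the corrected velocity is
divergence-free to the direct-solver tolerance after every step.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import momentum_rhs
from .grid import CartesianGrid, ScalarField, SymTensorField, VectorField
from .operators import (divergence, face_gradient, velocity_gradient,
                        zero_wall_faces)
from .poisson import build_poisson
from .solid import SolidProps, elastic_force

__all__ = ["FlowState", "MomentumSolver", "compute_dt", "q_criterion",
           "mean_flow_forcing", "StagnationError", "SolverError"]


class StagnationError(RuntimeError):
    pass


class SolverError(RuntimeError):
    pass


@dataclass
class FlowState:
    """Velocity, alternative pressure, forcing accumulator and clock."""
    u: VectorField
    p_rgh: ScalarField
    S: float = 0.0
    t: float = 0.0
    step: int = 0
    poisson_residual: float = 0.0

    def max_speed(self) -> float:
        return max(float(np.max(np.abs(c))) for c in self.u.comps)


def compute_dt(state: FlowState, grid: CartesianGrid, co: float,
               nu_max: float, G: float, rho: float = 1.0,
               floor: float = 1e-10) -> float:
    """Stable time step: CFL bound plus the explicit viscous and elastic
    wave bounds  3 nu dt / dx^2 < 1  and  sqrt(G/rho) dt / dx < 1."""
    dx = grid.dx
    umax = state.max_speed()
    bounds = []
    if umax > 0:
        bounds.append(co * dx / umax)
    if nu_max > 0:
        bounds.append(dx * dx / (3.0 * nu_max))
    if G > 0:
        bounds.append(dx / np.sqrt(G / rho))
    if not bounds:
        raise StagnationError("no active time-step bound")
    dt = min(bounds)
    if dt < floor:
        raise StagnationError(f"time step collapsed to {dt:.3e}")
    return dt


def q_criterion(u: VectorField) -> ScalarField:
    """Q = (|Omega|^2 - |S|^2) / 2 from the cell-centered velocity gradient
    (Frobenius norms); positive where rotation beats strain."""
    L = velocity_gradient(u)
    q = np.zeros(u.grid.shape3)
    for i in range(3):
        for j in range(3):
            Sij = 0.5 * (L[i, j] + L[j, i])
            Oij = 0.5 * (L[i, j] - L[j, i])
            q += Oij * Oij - Sij * Sij
    return ScalarField(u.grid, 0.5 * q, quantity="Q")


class MomentumSolver:
    """Driver for one momentum step with pressure projection.

    ``vel_bc``: per (axis, side) either ('wall', (vx, vy, vz)) for a no-slip
    (possibly moving) wall or ('zero-gradient',) for an open end; periodic
    axes need no entry.  ``p_dirichlet``: per (axis, side) fixed p_rgh value
    (projection increments vanish there).
    """

    def __init__(self, grid: CartesianGrid, nu_f: float, nu_s: float,
                 vel_bc=None, p_dirichlet=None, outer_correctors: int = 1,
                 rho: float = 1.0):
        self.grid = grid
        self.nu_f = nu_f
        self.nu_s = nu_s
        self.rho = rho
        self.vel_bc = dict(vel_bc or {})
        self.p_dirichlet = dict(p_dirichlet or {})
        self.outer = int(outer_correctors)
        self.poisson = build_poisson(grid, dirichlet=tuple(self.p_dirichlet))
        self._fluid = grid.fluid_mask()

    # ------------------------------------------------------------- padding
    def _pad_comp(self, arr: np.ndarray, comp: int) -> np.ndarray:
        g = self.grid
        out = arr
        for ax in range(3):
            pads = [(0, 0)] * 3
            pads[ax] = (2, 2)
            if g.periodic3[ax]:
                if comp == ax:
                    # duplicate node: unique nodes are 0..n-1
                    n = out.shape[ax] - 1
                    lo = out.take(np.arange(n - 2, n) % n, axis=ax,
                                  mode="wrap")
                    hi = out.take(np.arange(1, 3) % n, axis=ax, mode="wrap")
                    out = np.concatenate([lo, out, hi], axis=ax)
                else:
                    out = np.pad(out, pads, mode="wrap")
                continue
            bc_lo = self.vel_bc.get((ax, 0), ("wall", (0.0, 0.0, 0.0)))
            bc_hi = self.vel_bc.get((ax, 1), ("wall", (0.0, 0.0, 0.0)))
            out = np.pad(out, pads, mode="edge")
            for side, bc in ((0, bc_lo), (1, bc_hi)):
                if bc[0] == "zero-gradient":
                    continue  # edge replication is exactly zero-gradient
                vwall = bc[1][comp]
                n = out.shape[ax]
                for w in (1, 2):
                    gi = 2 - w if side == 0 else n - 3 + w
                    if comp == ax:
                        # boundary node sits on the wall; reflect oddly
                        ii = 2 + w if side == 0 else n - 3 - w
                    else:
                        ii = 1 + w if side == 0 else n - 2 - w
                    ref = out.take(ii, axis=ax)
                    sl = [slice(None)] * 3
                    sl[ax] = gi
                    out[tuple(sl)] = 2.0 * vwall - ref
        return np.ascontiguousarray(out)

    def _pad_scalar(self, arr: np.ndarray) -> np.ndarray:
        g = self.grid
        out = arr
        for ax in range(3):
            pads = [(0, 0)] * 3
            pads[ax] = (2, 2)
            mode = "wrap" if g.periodic3[ax] else "edge"
            out = np.pad(out, pads, mode=mode)
        return np.ascontiguousarray(out)

    # ------------------------------------------------------------------ BCs
    def apply_velocity_bc(self, u: VectorField):
        g = self.grid
        for (ax, side), bc in self.vel_bc.items():
            if g.periodic3[ax]:
                continue
            c = u.comps[ax]
            sl = [slice(None)] * 3
            sl[ax] = 0 if side == 0 else -1
            if bc[0] == "wall":
                c[tuple(sl)] = bc[1][ax]
            elif bc[0] == "zero-gradient":
                if (ax, side) in self.p_dirichlet:
                    # pressure inlet: the boundary-normal face is a
                    # projection degree of freedom, not copied
                    continue
                src = [slice(None)] * 3
                src[ax] = 1 if side == 0 else -2
                c[tuple(sl)] = c[tuple(src)]
        if g.wall_mask is not None:
            zero_wall_faces(u, g.wall_mask)
        u.sync_periodic()
        return u

    def _grad_p_faces(self, p: np.ndarray, values: bool = True):
        """Face pressure gradient including Dirichlet boundary faces.

        ``values=False`` treats the Dirichlet boundary value as zero (the
        increment problem)."""
        g = self.grid
        out = [face_gradient(p, g, ax) for ax in range(3)]
        for (ax, side), v in self.p_dirichlet.items():
            vv = v if values else 0.0
            c = out[ax]
            sl = [slice(None)] * 3
            adj = [slice(None)] * 3
            if side == 0:
                sl[ax] = 0
                adj[ax] = 0
                c[tuple(sl)] = 2.0 * (p[tuple(adj)] - vv) / g.dx
            else:
                sl[ax] = -1
                adj[ax] = -1
                c[tuple(sl)] = 2.0 * (vv - p[tuple(adj)]) / g.dx
        return out

    # ----------------------------------------------------------------- step
    def momentum_step(self, flow: FlowState, btilde: SymTensorField | None,
                      alpha: np.ndarray | None, props: SolidProps | None,
                      dt: float, S_axis: int = 0) -> FlowState:
        """Advance velocity and pressure by dt (alpha already advected).

        Explicit MUSCL advection + mixture-viscosity stress + elastic force
        + uniform forcing S, then the incremental pressure projection; the
        outer loop re-evaluates the explicit terms PIMPLE-style.
        """
        g = self.grid
        dx = g.dx
        u_n = [c.copy() for c in flow.u.comps]
        if alpha is None:
            a = np.zeros(g.shape3)
        else:
            a = alpha.data if isinstance(alpha, ScalarField) else alpha
        nu_s = self.nu_s if props is None else props.mu_s
        mu = a * nu_s + (1.0 - a) * self.nu_f  # kinematic (rho = 1 scale)
        mup = self._pad_scalar(mu)
        fel = None
        if btilde is not None and props is not None and props.G > 0:
            fel = elastic_force(btilde, a, props, rho=self.rho)

        u = flow.u
        p = flow.p_rgh.data
        for _ in range(max(1, self.outer)):
            up = self._pad_comp(u.comps[0], 0)
            vp = self._pad_comp(u.comps[1], 1)
            wp = self._pad_comp(u.comps[2], 2)
            ru = np.empty(g.face_shape(0))
            rv = np.empty(g.face_shape(1))
            rw = np.empty(g.face_shape(2))
            momentum_rhs(up, vp, wp, mup, dx, ru, rv, rw)
            rhs = [ru, rv, rw]
            gp = self._grad_p_faces(p, values=True)
            ustar = []
            for comp in range(3):
                r = rhs[comp] - gp[comp]
                if fel is not None:
                    r = r + fel[comp]
                if comp == S_axis and flow.S != 0.0:
                    r = r + flow.S
                ustar.append(u_n[comp] + dt * r)
            u = VectorField(g, ustar, quantity="u")
            self.apply_velocity_bc(u)
            div = divergence(u).data
            div[~self._fluid] = 0.0
            phi = self.poisson.solve(div / dt)
            p = p + phi
            gphi = self._grad_p_faces(phi, values=False)
            for comp in range(3):
                u.comps[comp] -= dt * gphi[comp]
            self.apply_velocity_bc(u)

        res = divergence(u).data
        res[~self._fluid] = 0.0
        resid = float(np.max(np.abs(res)))
        if not np.isfinite(resid):
            raise SolverError("projection produced non-finite divergence")
        return FlowState(u=u, p_rgh=ScalarField(g, p, quantity="p_rgh"),
                         S=flow.S, t=flow.t + dt, step=flow.step + 1,
                         poisson_residual=resid)

    # ------------------------------------------------------------- forcing
    def fluid_axial_faces(self, axis: int = 0) -> np.ndarray:
        """Mask of axis-faces lying between two fluid cells (or duplicates
        on the periodic seam)."""
        g = self.grid
        fl = self._fluid
        m = np.zeros(g.face_shape(axis), dtype=bool)
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        inner = [slice(None)] * 3
        inner[axis] = slice(1, -1)
        lo = fl.take(range(0, g.shape3[axis] - 1), axis=axis)
        hi = fl.take(range(1, g.shape3[axis]), axis=axis)
        m[tuple(inner)] = lo & hi
        if g.periodic3[axis]:
            first = [slice(None)] * 3
            last = [slice(None)] * 3
            first[axis] = 0
            last[axis] = -1
            seam = fl.take(0, axis=axis) & fl.take(-1, axis=axis)
            m[tuple(first)] = seam
            m[tuple(last)] = False  # the seam face is counted once
        return m


def mean_flow_forcing(flow: FlowState, solver: MomentumSolver,
                      target_mean: float, dt: float, axis: int = 0
                      ) -> tuple[FlowState, float]:
    """Uniform pseudo-pressure-gradient controller.

    After the corrector, nudge the bulk axial velocity to ``target_mean`` by
    a uniform source increment dS = (target - mean)/dt added to the axial
    momentum; the running S accumulator is the pressure-gradient readout
    (pressure drop = S * L).
    """
    faces = solver.fluid_axial_faces(axis)
    c = flow.u.comps[axis]
    mean = float(c[faces].mean())
    dS = (target_mean - mean) / dt
    c[faces] += dS * dt
    flow.u.sync_periodic()
    flow.S += dS
    return flow, mean
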