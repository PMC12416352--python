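"""End-to-end cases: lid-driven cavity FSI, forced pipe (Poiseuille),
torus-in-pipe transport, and the stenotic embolization test.

Every case shares the same time loop (Scheme: interface advection ->
B~ clip/evolution -> momentum with projection -> optional mean-flow
forcing).  The presets here are the scaled-down desk conditions documented
in the methods note; the full study-scale resolutions are exposed through the
configuration but not used by the test-suite presets.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .axisym import AxisymmetricPipeFlow
from .config import CaseConfig, config_hash
from .flow import (FlowState, MomentumSolver, SolverError, compute_dt,
                   mean_flow_forcing)
from .grid import CartesianGrid, ScalarField, SymTensorField, VectorField
from .io import load_checkpoint, save_checkpoint
from .particles import ParticleSpec, pipe_mask, rasterize, stenosis_mask
from .shape import (ShapeMetrics, bending_angles, centroid,
                    centroid_velocity, contour2d, cross_section_ellipses,
                    isosurface, local_frame, match_frame, orientation,
                    projected_circle_ratios)
from .solid import (BlowUpError, SolidProps, btilde_initial, clip_btilde,
                    evolve_btilde)
from .vof import VofInstabilityError, advect_alpha

log = logging.getLogger(__name__)

__all__ = ["ScenarioResult", "FSIDriver", "run_cavity", "run_poiseuille",
           "run_torus_in_pipe", "run_stenosis", "convergence_study",
           "TracerSet"]


@dataclass
class ScenarioResult:
    series: pd.DataFrame | None = None
    metrics: list[ShapeMetrics] = dfield(default_factory=list)
    contours: dict = dfield(default_factory=dict)
    tracers: dict = dfield(default_factory=dict)
    errors: dict = dfield(default_factory=dict)
    convergence: pd.DataFrame | None = None
    diverged: bool = False
    fail_time: float | None = None
    extra: dict = dfield(default_factory=dict)


class TracerSet:
    """Lagrangian markers advected with RK2 in the interpolated velocity
    (cavity verification only; 2D)."""

    def __init__(self, positions: np.ndarray):
        self.positions = np.asarray(positions, float)

    def __len__(self):
        return len(self.positions)

    def advance(self, u: VectorField, dt: float):
        def vel(p):
            return _interp_velocity_2d(u, p)
        p0 = self.positions
        k1 = vel(p0)
        k2 = vel(p0 + dt * k1)
        self.positions = p0 + 0.5 * dt * (k1 + k2)
        return self


def _interp_velocity_2d(u: VectorField, pts: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of the staggered velocity at points (N, 2)."""
    g = u.grid
    dx = g.dx
    nx, ny = g.shape3[0], g.shape3[1]
    out = np.zeros_like(pts)
    # ux on faces (i*dx, (j+1/2)dx)
    ux = u.comps[0][:, :, 0]
    fx = pts[:, 0] / dx
    fy = pts[:, 1] / dx - 0.5
    i0 = np.clip(np.floor(fx).astype(int), 0, nx - 1)
    j0 = np.clip(np.floor(fy).astype(int), 0, ny - 2)
    tx = np.clip(fx - i0, 0, 1)
    ty = np.clip(fy - j0, 0, 1)
    out[:, 0] = ((1 - tx) * (1 - ty) * ux[i0, j0]
                 + tx * (1 - ty) * ux[i0 + 1, j0]
                 + (1 - tx) * ty * ux[i0, j0 + 1]
                 + tx * ty * ux[i0 + 1, j0 + 1])
    uy = u.comps[1][:, :, 0]
    fx = pts[:, 0] / dx - 0.5
    fy = pts[:, 1] / dx
    i0 = np.clip(np.floor(fx).astype(int), 0, nx - 2)
    j0 = np.clip(np.floor(fy).astype(int), 0, ny - 1)
    tx = np.clip(fx - i0, 0, 1)
    ty = np.clip(fy - j0, 0, 1)
    out[:, 1] = ((1 - tx) * (1 - ty) * uy[i0, j0]
                 + tx * (1 - ty) * uy[i0, j0 + 1]
                 + (1 - tx) * ty * uy[i0 + 1, j0]
                 + tx * ty * uy[i0 + 1, j0 + 1])
    return out


class FSIDriver:
    """Shared time loop of the full-Eulerian solver.

    Scheme per step: adaptive dt -> geometric alpha advection -> minimum
    volume-fraction clip of B~ -> WENO/trapezoidal B~ evolution -> momentum
    predictor + projection -> optional mean-flow forcing controller.
    """

    def __init__(self, grid: CartesianGrid, config: CaseConfig,
                 props: SolidProps | None = None,
                 alpha: ScalarField | None = None,
                 vel_bc=None, p_dirichlet=None, forcing_target=None):
        self.grid = grid
        self.config = config
        self.props = props
        self.msolver = MomentumSolver(
            grid, nu_f=config.nu_f, nu_s=config.nu_s, vel_bc=vel_bc,
            p_dirichlet=p_dirichlet,
            outer_correctors=config.outer_correctors)
        self.alpha = alpha if alpha is not None else \
            ScalarField(grid, quantity="alpha")
        self.has_solid = props is not None and float(self.alpha.data.sum()) > 0
        if self.has_solid:
            self.btilde = btilde_initial(grid, self.alpha, props)
        else:
            self.btilde = None
        self.flow = FlowState(u=VectorField(grid),
                              p_rgh=ScalarField(grid, quantity="p_rgh"))
        self.msolver.apply_velocity_bc(self.flow.u)
        self.forcing_target = forcing_target
        self.rec = None
        self.history: list[dict] = []

    # ------------------------------------------------------------ stepping
    def _dt(self) -> float:
        G = self.props.G if self.props else 0.0
        nu_max = max(self.config.nu_f, self.config.nu_s)
        return compute_dt(self.flow, self.grid, self.config.co, nu_max, G)

    def step(self) -> float:
        dt = self._dt()
        cfg = self.config
        if self.has_solid:
            self.alpha, self.rec = advect_alpha(
                self.alpha, self.flow.u, dt, step=self.flow.step,
                reconstruction=self.rec,
                rdf_iterations=cfg.rdf_iterations)
            clip_btilde(self.btilde, self.alpha, self.props,
                        clip_alpha=False)
            self.btilde = evolve_btilde(self.btilde, self.flow.u, dt,
                                        alpha=self.alpha)
        self.flow = self.msolver.momentum_step(
            self.flow, self.btilde, self.alpha, self.props, dt)
        mean = math.nan
        if self.forcing_target is not None:
            self.flow, mean = mean_flow_forcing(
                self.flow, self.msolver, self.forcing_target, dt)
        self.history.append({"t": self.flow.t, "dt": dt, "S": self.flow.S,
                             "mean_u": mean,
                             "solid_volume": float(self.alpha.data.sum())
                             * self.grid.cell_volume,
                             "div_residual": self.flow.poisson_residual})
        return dt

    def run(self, t_end: float, sample_every: float | None = None,
            on_sample=None, max_steps: int = 2_000_000):
        next_sample = 0.0
        if sample_every is not None and on_sample is not None:
            on_sample(self)
            next_sample = sample_every
        while self.flow.t < t_end - 1e-12 and self.flow.step < max_steps:
            self.step()
            if sample_every is not None and on_sample is not None and \
                    self.flow.t + 1e-12 >= next_sample:
                on_sample(self)
                next_sample += sample_every
        return self

    # --------------------------------------------------------- checkpoints
    def checkpoint_state(self) -> dict:
        st = {
            "u0": self.flow.u.comps[0], "u1": self.flow.u.comps[1],
            "u2": self.flow.u.comps[2], "p": self.flow.p_rgh.data,
            "alpha": self.alpha.data,
            "S": float(self.flow.S), "t": float(self.flow.t),
            "step": int(self.flow.step),
            "config": config_hash(self.config),
        }
        if self.btilde is not None:
            st["btilde"] = self.btilde.data
        if self.rec is not None and self.rec.normal_cache is not None:
            st["normal_cache"] = self.rec.normal_cache
        return st

    def save(self, path):
        return save_checkpoint(path, self.checkpoint_state())

    def restore(self, path):
        st = load_checkpoint(path)
        if st["config"] != config_hash(self.config):
            raise ValueError("checkpoint does not match this configuration")
        g = self.grid
        self.flow = FlowState(
            u=VectorField(g, [st["u0"], st["u1"], st["u2"]]),
            p_rgh=ScalarField(g, st["p"], quantity="p_rgh"),
            S=float(st["S"]), t=float(st["t"]), step=int(st["step"]))
        self.alpha = ScalarField(g, st["alpha"], quantity="alpha")
        if "btilde" in st:
            self.btilde = SymTensorField(g, st["btilde"])
        if "normal_cache" in st:
            from .vof import InterfaceReconstruction
            self.rec = InterfaceReconstruction(
                np.zeros((0, 3), dtype=int), np.zeros((0, 3)), np.zeros(0),
                st["normal_cache"])
        else:
            self.rec = None
        return self


# ------------------------------------------------------------------ cavity

def cavity_config(n: int = 64, t_end: float = 20.0, **kw) -> CaseConfig:
    """Lid-driven cavity FSI benchmark: unit box, lid speed 1, nu = 0.01
    everywhere, G = 0.05, disk of radius 0.2 at (0.6, 0.5), B~ reset to the
    zero tensor."""
    defaults = dict(
        kind="cavity", re=50.0, viscosity_ratio=1.0, G=0.05,
        grid_shape=(n, n), grid_lengths=(1.0, 1.0),
        btilde_reset="zero", t_end=t_end, lid_velocity=1.0,
    )
    defaults.update(kw)
    return CaseConfig(**defaults)


def _cavity_alpha(grid: CartesianGrid, center=(0.6, 0.5), radius=0.2,
                  supersampling=3) -> ScalarField:
    s = supersampling
    dx = grid.dx
    offs = (np.arange(s) + 0.5) / s
    nx, ny = grid.shape3[0], grid.shape3[1]
    xs = (np.arange(nx)[:, None] + offs[None, :]).ravel() * dx
    ys = (np.arange(ny)[:, None] + offs[None, :]).ravel() * dx
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    inside = (X - center[0]) ** 2 + (Y - center[1]) ** 2 < radius ** 2
    frac = inside.reshape(nx, s, ny, s).mean(axis=(1, 3))
    return ScalarField(grid, frac[:, :, None], quantity="alpha")


def build_cavity(config: CaseConfig) -> FSIDriver:
    n = config.grid_shape[0]
    grid = CartesianGrid((n, n), (1.0, 1.0), periodic=(False, False))
    props = SolidProps(G=config.G, mu_s=config.nu_s,
                       alpha_min=config.alpha_min, reset="zero")
    alpha = _cavity_alpha(grid)
    vel_bc = {
        (0, 0): ("wall", (0.0, 0.0, 0.0)),
        (0, 1): ("wall", (0.0, 0.0, 0.0)),
        (1, 0): ("wall", (0.0, 0.0, 0.0)),
        (1, 1): ("wall", (config.lid_velocity, 0.0, 0.0)),
    }
    return FSIDriver(grid, config, props=props, alpha=alpha, vel_bc=vel_bc)


def run_cavity(config: CaseConfig | None = None, n: int | None = None,
               t_end: float | None = None, sample_every: float = 0.05,
               contour_times=(), n_tracers: int = 200) -> ScenarioResult:
    """Deformable-disk-in-cavity verification.

    Returns the centroid trajectory series, alpha = 0.5 contours at the
    requested times, and Lagrangian tracer positions."""
    if config is None:
        config = cavity_config(n=n or 64, t_end=t_end if t_end is not None
                               else 20.0)
    drv = build_cavity(config)
    rng = np.random.default_rng(config.seed)
    a2 = drv.alpha.view2d()
    cand = np.argwhere(a2 > 0.5)
    if len(cand) and n_tracers > 0:
        pick = cand[rng.choice(len(cand), size=min(n_tracers, len(cand)),
                               replace=False)]
        pos = (pick + 0.5) * drv.grid.dx
        tracers = TracerSet(pos)
    else:
        tracers = TracerSet(np.zeros((0, 2)))
    rows = []
    contours = {}
    tracer_snaps = {}
    ctimes = sorted(contour_times)
    pending = list(ctimes)

    def sample(d: FSIDriver):
        xc = centroid(d.alpha)
        uc = centroid_velocity(d.alpha, d.flow.u)
        rows.append((d.flow.t, xc[0], xc[1], uc[0], uc[1],
                     float(d.alpha.data.sum()) * d.grid.cell_volume))
        while pending and d.flow.t + 1e-9 >= pending[0]:
            tq = pending.pop(0)
            contours[tq] = contour2d(d.alpha)
            tracer_snaps[tq] = tracers.positions.copy()

    # wrap stepping to advect tracers with the flow
    orig_step = drv.step

    def step_with_tracers():
        dt = orig_step()
        if len(tracers):
            tracers.advance(drv.flow.u, dt)
        return dt

    drv.step = step_with_tracers
    result = ScenarioResult()
    try:
        drv.run(config.t_end, sample_every=sample_every, on_sample=sample)
    except (BlowUpError, SolverError, VofInstabilityError) as e:
        result.diverged = True
        result.fail_time = drv.flow.t
        result.errors["failure"] = str(e)
    result.series = pd.DataFrame(
        rows, columns=["t", "xc_x", "xc_y", "uc_x", "uc_y", "solid_volume"])
    result.contours = contours
    result.tracers = tracer_snaps
    result.extra["driver"] = drv
    return result


# -------------------------------------------------------------- poiseuille

def run_poiseuille(n_radial: int = 64, re: float = 50.0, co: float = 0.1,
                   target_mean: float = 0.5, tol: float = 1e-10
                   ) -> ScenarioResult:
    """Forced pipe flow on the axisymmetric reduction, integrated to steady
    state; reports the L2 error against the analytic profile and the steady
    forcing."""
    f = AxisymmetricPipeFlow(n_radial=n_radial, re=re, co=co,
                             target_mean=target_mean)
    res = f.run_to_steady(tol=tol)
    out = ScenarioResult()
    out.series = pd.DataFrame({"r": res.r, "u": res.u})
    out.errors = {"l2": res.l2, "S": res.S, "bulk": res.bulk,
                  "S_analytic": f.analytic_forcing, "steps": res.steps}
    out.extra["solver"] = f
    return out


# ------------------------------------------------------------ torus in pipe

def pipe_config(psi0_deg: float = 45.0, n_across: int = 32,
                length: float = 3.0, t_end: float = 8.0,
                r: float = 0.125, R: float = 0.3,
                y0: float = 0.5, G: float = 10.0, **kw) -> CaseConfig:
    """Scaled-down torus-in-pipe preset.

    96 x 32 x 32 cells over a 3-diameter periodic pipe; the torus is scaled
    to r = 0.125 (within the published parameter range) so 8 cells span the
    tube diameter.  G = 10 (rho U^2 units) corresponds to 100 Pa.
    """
    nx = int(round(length * n_across))
    particle = ParticleSpec("torus", {"r": r, "R": R},
                            (length / 2.0, y0, 0.5), psi0_deg)
    defaults = dict(kind="pipe", re=50.0, G=G, t_end=t_end,
                    grid_shape=(nx, n_across, n_across),
                    grid_lengths=(length, 1.0, 1.0), particle=particle)
    defaults.update(kw)
    return CaseConfig(**defaults)


def build_pipe(config: CaseConfig) -> FSIDriver:
    mask = None
    grid0 = CartesianGrid(config.grid_shape, config.grid_lengths,
                          periodic=(True, False, False))
    mask = pipe_mask(grid0, radius=0.5)
    grid = CartesianGrid(config.grid_shape, config.grid_lengths,
                         periodic=(True, False, False), wall_mask=mask)
    props = SolidProps(G=config.G, mu_s=config.nu_s,
                       alpha_min=config.alpha_min, reset=config.btilde_reset)
    alpha = rasterize(config.particle, grid) if config.particle else None
    vel_bc = {(1, 0): ("wall", (0.0, 0.0, 0.0)),
              (1, 1): ("wall", (0.0, 0.0, 0.0)),
              (2, 0): ("wall", (0.0, 0.0, 0.0)),
              (2, 1): ("wall", (0.0, 0.0, 0.0))}
    drv = FSIDriver(grid, config, props=props, alpha=alpha, vel_bc=vel_bc,
                    forcing_target=config.mean_velocity)
    if config.perturbation > 0:
        rng = np.random.default_rng(config.seed)
        for c in drv.flow.u.comps:
            c += config.perturbation * rng.standard_normal(c.shape)
        drv.msolver.apply_velocity_bc(drv.flow.u)
    return drv


def run_torus_in_pipe(config: CaseConfig, sample_every: float | None = None
                      ) -> ScenarioResult:
    """Transport + deformation of a torus in the forced periodic pipe.

    Emits the ShapeMetrics series (orientation angle, centroid, cross-
    section aspect ratios, bending angles, projected-circle ratios) and the
    forcing (pressure-gradient) history."""
    drv = build_pipe(config)
    sample_every = sample_every or config.output_every
    metrics: list[ShapeMetrics] = []
    state = {"prev_n": None}
    result = ScenarioResult()

    def sample(d: FSIDriver):
        try:
            surf = isosurface(d.alpha)
            xc_dom = centroid(d.alpha)
            uc = centroid_velocity(d.alpha, d.flow.u)
            xc = match_frame(xc_dom, surf.verts, d.grid)
            n, psi, degen = orientation(surf, xc, prev_n=state["prev_n"])
            state["prev_n"] = n
            frame = local_frame(n)
            ell = cross_section_ellipses(surf, frame, xc)
            bm, bp = bending_angles(ell, xc, frame)
            inner, outer = projected_circle_ratios(surf, frame, xc)
            metrics.append(ShapeMetrics(
                time=d.flow.t, centroid=xc_dom, centroid_velocity=uc,
                psi_deg=psi,
                aspect_forward=_ar(ell, "forward"),
                aspect_back=_ar(ell, "back"),
                aspect_right=_ar(ell, "right"),
                aspect_left=_ar(ell, "left"),
                bend_meridian_deg=bm, bend_prime_vertical_deg=bp,
                projected_inner_ratio=inner, projected_outer_ratio=outer,
                degenerate_orientation=degen))
        except ValueError as e:   # degenerate surface etc.
            log.warning("metric sampling failed at t=%.3f: %s", d.flow.t, e)

    try:
        drv.run(config.t_end, sample_every=sample_every, on_sample=sample)
    except (BlowUpError, SolverError, VofInstabilityError) as e:
        result.diverged = True
        result.fail_time = drv.flow.t
        result.errors["failure"] = str(e)
    result.metrics = metrics
    result.series = pd.DataFrame(drv.history)
    result.extra["driver"] = drv
    return result


def _ar(ell, name):
    f = ell.get(name)
    return None if f is None else f.aspect_ratio


# ---------------------------------------------------------------- stenosis

def stenosis_config(shape: str = "torus", n_across: int = 24,
                    length: float = 6.0, t_end: float = 6.0,
                    y0: float = 0.5, psi0_deg: float = 45.0,
                    x0: float = 0.7, **kw) -> CaseConfig:
    """Stenotic-pipe embolization preset (lengths in inlet-diameter-halves,
    i.e. millimetres of the published geometry: inlet radius 1, throat 0.5,
    length 6).

    The four particle shapes share the Table-of-shapes surface area: torus
    (r=0.1, R=0.3) and its area-matched disk, sphere and ellipsoid.
    """
    from .particles import match_area
    torus = ParticleSpec("torus", {"r": 0.1, "R": 0.3}, (x0, 1.0 - y0, 1.0),
                         psi0_deg)
    particle = torus if shape == "torus" else match_area(torus, shape)
    nx = int(round(length * n_across / 2.0))
    defaults = dict(kind="stenosis", re=50.0, G=10.0, t_end=t_end,
                    grid_shape=(nx, n_across, n_across),
                    grid_lengths=(length, 2.0, 2.0), particle=particle,
                    stenosis_length=length)
    defaults.update(kw)
    return CaseConfig(**defaults)


def build_stenosis(config: CaseConfig) -> FSIDriver:
    grid0 = CartesianGrid(config.grid_shape, config.grid_lengths,
                          periodic=(False, False, False))
    mask = stenosis_mask(grid0, config.stenosis_length,
                         config.stenosis_inlet_radius,
                         config.stenosis_throat_radius)
    grid = CartesianGrid(config.grid_shape, config.grid_lengths,
                         periodic=(False, False, False), wall_mask=mask)
    props = SolidProps(G=config.G, mu_s=config.nu_s,
                       alpha_min=config.alpha_min, reset=config.btilde_reset)
    alpha = rasterize(config.particle, grid) if config.particle else None
    vel_bc = {(0, 0): ("zero-gradient",), (0, 1): ("zero-gradient",),
              (1, 0): ("wall", (0.0, 0.0, 0.0)),
              (1, 1): ("wall", (0.0, 0.0, 0.0)),
              (2, 0): ("wall", (0.0, 0.0, 0.0)),
              (2, 1): ("wall", (0.0, 0.0, 0.0))}
    # pressure-driven: inlet reservoir at 5.5, outlet reference 0 (the
    # boundary-normal faces are projection degrees of freedom)
    p_dirichlet = {(0, 0): config.inlet_pressure, (0, 1): 0.0}
    return FSIDriver(grid, config, props=props, alpha=alpha, vel_bc=vel_bc,
                     p_dirichlet=p_dirichlet)


def stenosis_base_flow(config: CaseConfig, t_develop: float = 3.0,
                       t_reference: float | None = None):
    """Particle-free developed flow through the stenosis.

    Returns the (u, p) release state for the particle runs plus the
    continued particle-free pressure-drop series over the measurement
    window, so the particle's excess pressure drop can be isolated from
    the residual base-flow transient."""
    cfg = CaseConfig(**{**config.__dict__, "particle": None})
    drv = build_stenosis(cfg)
    drv.run(t_develop)
    state = {"u": [c.copy() for c in drv.flow.u.comps],
             "p": drv.flow.p_rgh.data.copy(), "t_develop": t_develop}
    if t_reference is None:
        t_reference = config.t_end
    g = drv.grid
    fluid = g.fluid_mask()
    L = cfg.stenosis_length
    i_up = int(round(0.25 * L / g.dx))
    i_dn = min(int(round(0.75 * L / g.dx)), g.shape3[0] - 1)
    ts, dps = [], []
    while drv.flow.t < t_develop + t_reference - 1e-12:
        drv.step()
        p = drv.flow.p_rgh.data
        ts.append(drv.flow.t - t_develop)
        dps.append(float(p[i_up][fluid[i_up]].mean()
                         - p[i_dn][fluid[i_dn]].mean()))
    state["baseline_t"] = np.asarray(ts)
    state["baseline_dp"] = np.asarray(dps)
    return state


def run_stenosis(config: CaseConfig, stop_x: float | None = None,
                 base_state: dict | None = None) -> ScenarioResult:
    """Pressure-driven passage of one particle through the stenosis.

    With ``base_state`` (from :func:`stenosis_base_flow`) the particle is
    released into the developed flow.  Records the stenotic-segment
    pressure-drop and outlet flow-rate series; a solver blow-up is
    reported as a truncated series flagged 'diverged' rather than an
    exception."""
    drv = build_stenosis(config)
    if base_state is not None:
        g = drv.grid
        drv.flow = FlowState(
            u=VectorField(g, [c.copy() for c in base_state["u"]]),
            p_rgh=ScalarField(g, base_state["p"].copy(),
                              quantity="p_rgh"))
        drv.msolver.apply_velocity_bc(drv.flow.u)
    g = drv.grid
    fluid = g.fluid_mask()
    fluid_out = fluid[-1]
    dx = g.dx
    L = config.stenosis_length
    i_up = int(round(0.25 * L / dx))            # taper entry plane
    i_dn = min(int(round(0.75 * L / dx)), g.shape3[0] - 1)
    rows = []
    result = ScenarioResult()
    if stop_x is None:
        stop_x = L / 2.0 + 1.6

    def record(d: FSIDriver):
        p = d.flow.p_rgh.data
        # pressure drop across the stenotic segment (the end-to-end drop is
        # pinned by the two pressure boundaries)
        dp = float(p[i_up][fluid[i_up]].mean()
                   - p[i_dn][fluid[i_dn]].mean())
        ux_out = d.flow.u.comps[0][-1]
        qdot = float(ux_out[fluid_out].sum()) * dx * dx
        rows.append((d.flow.t, dp, qdot))

    try:
        while drv.flow.t < config.t_end - 1e-12:
            drv.step()
            record(drv)
            if drv.has_solid and drv.flow.step % 10 == 0:
                xc = centroid(drv.alpha)
                if xc[0] > stop_x:
                    result.extra["passed"] = True
                    break
    except (BlowUpError, SolverError, VofInstabilityError) as e:
        result.diverged = True
        result.fail_time = drv.flow.t
        result.errors["failure"] = str(e)
    df = pd.DataFrame(rows, columns=["t", "pressure_drop", "flow_rate"])
    if base_state is not None and "baseline_t" in base_state and len(df):
        base = np.interp(df["t"], base_state["baseline_t"],
                         base_state["baseline_dp"])
        df["excess_pressure_drop"] = df["pressure_drop"] - base
    result.series = df
    result.extra["driver"] = drv
    return result


# -------------------------------------------------------------- convergence

def convergence_study(resolutions=(16, 32, 64), reference: int = 128,
                      t_end: float = 5.0, sample_every: float = 0.05,
                      runner=None) -> pd.DataFrame:
    """Centroid-trajectory self-convergence of the cavity case.

    L2 and Linf errors versus the finest grid, per the centroid-error norms,
    plus the fitted order (slope of log error vs log N).
    """
    if runner is None:
        def runner(n):
            return run_cavity(n=n, t_end=t_end, sample_every=sample_every,
                              n_tracers=0)
    runs = {}
    for n in list(resolutions) + [reference]:
        runs[n] = runner(n).series
    ref = runs[reference]
    t_ref = ref["t"].to_numpy()
    xy_ref = ref[["xc_x", "xc_y"]].to_numpy()
    rows = []
    for n in resolutions:
        s = runs[n]
        t = s["t"].to_numpy()
        xy = s[["xc_x", "xc_y"]].to_numpy()
        xi = np.stack([np.interp(t_ref, t, xy[:, k]) for k in range(2)],
                      axis=1)
        d = np.linalg.norm(xi - xy_ref, axis=1)
        rows.append((n, float(np.sqrt(np.mean(d ** 2))), float(d.max())))
    df = pd.DataFrame(rows, columns=["N", "L2", "Linf"])
    if len(df) >= 2:
        for col in ("L2", "Linf"):
            slope = np.polyfit(np.log(df["N"]), np.log(df[col]), 1)[0]
            df.attrs[f"order_{col}"] = float(-slope)
    return df
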