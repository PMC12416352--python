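"""Eulerian solid state: the corrected left Cauchy-Green tensor.

The solid's strain is carried as B~ = alpha^beta B, the volume-fraction
corrected left Cauchy-Green tensor (beta = 1/2 for an incompressible solid).
It obeys the transport equation

    dB~/dt + u . grad B~ = L B~ + B~ L^T,      L = grad u,

discretized with componentwise third-order WENO upwinding in space and a
trapezoidal (Crank-Nicolson style) predictor/single-corrector pass in time.
The Neo-Hookean deviatoric Cauchy stress contribution enters the momentum
equation as (G / rho) div( alpha^(1-beta) dev B~ ) in conservative flux form.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import weno3_advect
from .grid import CartesianGrid, ScalarField, SymTensorField, VectorField
from .operators import cell_centered_velocity

__all__ = ["SolidProps", "evolve_btilde", "clip_btilde", "elastic_force",
           "BlowUpError", "btilde_initial"]


class BlowUpError(RuntimeError):
    """Solid state exceeded the sanity bound (|B~| > 1e6)."""

    def __init__(self, msg, state=None):
        super().__init__(msg)
        self.state = state


@dataclass
class SolidProps:
    """Material and numerical parameters of the visco-hyperelastic solid.

    ``G`` and ``mu_s`` are dimensionless (G* = G / (rho U^2), see config for
    the conversion from Pa).  ``beta`` must stay at 1/2 for incompressibility
    unless explicitly overridden; ``alpha_min`` gates where the solid state is
    meaningful, cells below it are reset to ``reset`` ('unit' or 'zero').
    """
    G: float
    mu_s: float
    beta: float = 0.5
    alpha_min: float = 0.1
    reset: str = "unit"
    allow_beta_override: bool = False

    def __post_init__(self):
        if self.reset not in ("unit", "zero"):
            raise ValueError("reset must be 'unit' or 'zero'")
        if not (0.0 < self.alpha_min < 0.5):
            raise ValueError("alpha_min must lie in (0, 0.5)")
        if abs(self.beta - 0.5) > 1e-14 and not self.allow_beta_override:
            raise ValueError("beta must equal 1/2 (incompressibility); "
                             "set allow_beta_override to experiment")
        if self.G < 0 or self.mu_s < 0:
            raise ValueError("G and mu_s must be non-negative")


def btilde_initial(grid: CartesianGrid, alpha, props: SolidProps
                   ) -> SymTensorField:
    """Undeformed initial state.

    'zero' reset mode: B~ = alpha^beta I (B = I inside the solid, zero in the
    fluid); 'unit' mode: B~ = I everywhere (the pipe-case convention, inert in
    the fluid because dev I = 0).
    """
    a = alpha.data if isinstance(alpha, ScalarField) else np.asarray(alpha)
    if props.reset == "unit":
        return SymTensorField.identity(grid)
    return SymTensorField.identity(grid, scale=np.maximum(a, 0.0) ** props.beta)


# ------------------------------------------------------------------ banding

class _Band:
    """Axis-aligned bounding box (with margin) around the solid, supporting
    periodic wrap.  Extraction yields contiguous copies for the kernels."""

    def __init__(self, grid: CartesianGrid, alpha: np.ndarray, margin: int = 4):
        self.grid = grid
        self.ranges = []
        for ax in range(3):
            n = grid.shape3[ax]
            other = tuple(a for a in range(3) if a != ax)
            present = np.any(alpha > 1e-9, axis=other)
            if not present.any() or n == 1:
                self.ranges.append((0, n))
                continue
            idx = np.where(present)[0]
            if grid.periodic3[ax] and idx[0] == 0 and idx[-1] == n - 1 \
                    and len(idx) < n:
                # wrapped: find the largest empty gap
                gaps = np.where(~present)[0]
                start = gaps[-1] + 1
                stop = gaps[0] + n
                lo, hi = start - margin, stop + margin
            else:
                lo, hi = idx[0] - margin, idx[-1] + 1 + margin
            if grid.periodic3[ax]:
                if hi - lo >= n:
                    lo, hi = 0, n
            else:
                lo = max(lo, 0)
                hi = min(hi, n)
            self.ranges.append((int(lo), int(hi)))

    def take(self, arr: np.ndarray, pad: int = 0) -> np.ndarray:
        """Extract the band (+pad ghost layers) from a cell-centered array;
        wraps on periodic axes, replicates edges elsewhere."""
        out = arr
        off = arr.ndim - 3
        for ax in range(3):
            lo, hi = self.ranges[ax]
            mode = "wrap" if self.grid.periodic3[ax] else "clip"
            out = out.take(range(lo - pad, hi + pad), axis=ax + off, mode=mode)
        return np.ascontiguousarray(out)

    def put(self, arr: np.ndarray, sub: np.ndarray):
        off = arr.ndim - 3
        grids = []
        for d in range(arr.ndim):
            if d < off:
                grids.append(np.arange(arr.shape[d]))
            else:
                lo, hi = self.ranges[d - off]
                grids.append(np.arange(lo, hi) % self.grid.shape3[d - off])
        arr[np.ix_(*grids)] = sub


def _velocity_gradient_sub(ucc_pad: list[np.ndarray], dx: float
                           ) -> np.ndarray:
    """L[i,j] on the band interior from 1-ghost-padded centered velocity."""
    shape = tuple(s - 2 for s in ucc_pad[0].shape)
    L = np.zeros((3, 3) + shape)
    core = (slice(1, -1),) * 3
    for i in range(3):
        for j in range(3):
            sl_hi = [slice(1, -1)] * 3
            sl_lo = [slice(1, -1)] * 3
            sl_hi[j] = slice(2, None)
            sl_lo[j] = slice(None, -2)
            L[i, j] = (ucc_pad[i][tuple(sl_hi)]
                       - ucc_pad[i][tuple(sl_lo)]) / (2 * dx)
    return L


def _source(L: np.ndarray, B: np.ndarray) -> np.ndarray:
    """(L B + B L^T) for stacked symmetric components
    (xx, yy, zz, xy, xz, yz)."""
    xx, yy, zz, xy, xz, yz = B
    S = np.empty_like(B)
    S[0] = 2 * (L[0, 0] * xx + L[0, 1] * xy + L[0, 2] * xz)
    S[1] = 2 * (L[1, 0] * xy + L[1, 1] * yy + L[1, 2] * yz)
    S[2] = 2 * (L[2, 0] * xz + L[2, 1] * yz + L[2, 2] * zz)
    S[3] = (L[0, 0] * xy + L[0, 1] * yy + L[0, 2] * yz
            + L[1, 0] * xx + L[1, 1] * xy + L[1, 2] * xz)
    S[4] = (L[0, 0] * xz + L[0, 1] * yz + L[0, 2] * zz
            + L[2, 0] * xx + L[2, 1] * xy + L[2, 2] * xz)
    S[5] = (L[1, 0] * xz + L[1, 1] * yz + L[1, 2] * zz
            + L[2, 0] * xy + L[2, 1] * yy + L[2, 2] * yz)
    return S


def _pad_band(band: _Band, data: np.ndarray, pad: int) -> np.ndarray:
    return band.take(data, pad=pad)


def evolve_btilde(btilde: SymTensorField, u: VectorField, dt: float,
                  alpha=None, band_margin: int = 4) -> SymTensorField:
    """Advance B~ by dt with frozen velocity u.

    WENO3 upwind advection plus the stretching source, integrated with a
    trapezoidal predictor/corrector (one fixed-point pass): second order in
    time.  If ``alpha`` is given, work is restricted to a bounding band
    around the solid (exact when paired with the per-step clip, which resets
    B~ outside the solid anyway).
    """
    grid = btilde.grid
    dx = grid.dx
    if alpha is not None:
        a = alpha.data if isinstance(alpha, ScalarField) else alpha
        band = _Band(grid, a, margin=band_margin)
        if all(hi - lo == n for (lo, hi), n
               in zip(band.ranges, grid.shape3)):
            band = None
    else:
        band = None

    ucc = cell_centered_velocity(u)

    if band is None:
        from .operators import velocity_gradient
        L = velocity_gradient(u)
        Bfull = btilde.data

        def rhs(B):
            Bp = B
            for ax in range(3):
                mode = "wrap" if grid.periodic3[ax] else "edge"
                pads = [(0, 0)] * 4
                pads[ax + 1] = (2, 2)
                Bp = np.pad(Bp, pads, mode=mode)
            out = np.empty_like(B)
            weno3_advect(np.ascontiguousarray(Bp),
                         np.ascontiguousarray(ucc[0]),
                         np.ascontiguousarray(ucc[1]),
                         np.ascontiguousarray(ucc[2]), dx, out)
            return out + _source(L, B)

        B0 = Bfull
        B1 = B0 + dt * rhs(B0)
        Bn = B0 + 0.5 * dt * (rhs(B0) + rhs(B1))
    else:
        ucc_pad = [band.take(c, pad=1) for c in ucc]
        L = _velocity_gradient_sub(ucc_pad, dx)
        u_sub = [np.ascontiguousarray(c[1:-1, 1:-1, 1:-1]) for c in ucc_pad]
        B0 = band.take(btilde.data, pad=0)

        def rhs(B):
            Bp = np.pad(B, [(0, 0)] + [(2, 2)] * 3, mode="edge")
            out = np.empty_like(B)
            weno3_advect(np.ascontiguousarray(Bp), u_sub[0], u_sub[1],
                         u_sub[2], dx, out)
            return out + _source(L, B)

        r0 = rhs(B0)
        B1 = B0 + dt * r0
        Bn_sub = B0 + 0.5 * dt * (r0 + rhs(B1))
        Bn = btilde.data.copy()
        band.put(Bn, Bn_sub)

    mx = np.max(np.abs(Bn))
    if not np.isfinite(mx) or mx > 1e6:
        raise BlowUpError(f"|B~| reached {mx:.3e}",
                          state={"max_abs": float(mx)})
    out_field = SymTensorField(grid, Bn, btilde.spec, btilde.quantity)
    return out_field


def clip_btilde(btilde: SymTensorField, alpha, props: SolidProps,
                clip_alpha: bool = True):
    """Apply the minimum-volume-fraction rule.

    Cells with alpha strictly below ``props.alpha_min`` get B~ reset to the
    zero or unit tensor.  With ``clip_alpha`` the volume fraction is zeroed
    there too (the literal rule); the scenario drivers disable that to keep
    the interface-skin mass (see methods note on conservation).
    """
    a_field = alpha if isinstance(alpha, ScalarField) else None
    a = a_field.data if a_field is not None else np.asarray(alpha)
    low = a < props.alpha_min
    if props.reset == "unit":
        for i in range(3):
            btilde.data[i][low] = 1.0
        for i in range(3, 6):
            btilde.data[i][low] = 0.0
    else:
        btilde.data[:, low] = 0.0
    if clip_alpha:
        a[low] = 0.0
    return btilde, (a_field if a_field is not None else a)


def _face_div_sym(M: np.ndarray, grid: CartesianGrid, comp: int
                  ) -> np.ndarray:
    """Conservative divergence of the symmetric tensor M, evaluated on the
    faces of velocity component ``comp``.

    Normal entries difference the two flanking cells; shear entries are
    averaged to the cell edges (2x2 cell mean) so the fluxes telescope and
    the total elastic momentum on a periodic box vanishes to round-off.
    """
    dx = grid.dx
    names = {0: ("xx", "xy", "xz"), 1: ("xy", "yy", "yz"),
             2: ("xz", "yz", "zz")}[comp]
    order = {"xx": 0, "yy": 1, "zz": 2, "xy": 3, "xz": 4, "yz": 5}
    out = np.zeros(grid.face_shape(comp))
    interior = [slice(None)] * 3
    interior[comp] = slice(1, -1)
    low_faces = [slice(None)] * 3
    low_faces[comp] = slice(None, -1)

    for ax, name in enumerate(names):
        Mc = M[order[name]]
        if ax == comp:
            out[tuple(interior)] += np.diff(Mc, axis=comp) / dx
            if grid.periodic3[comp]:
                first = [slice(None)] * 3
                first[comp] = 0
                lo = [slice(None)] * 3
                hi = [slice(None)] * 3
                lo[comp] = -1
                hi[comp] = 0
                out[tuple(first)] += (Mc[tuple(hi)] - Mc[tuple(lo)]) / dx
        else:
            if grid.shape3[ax] == 1:
                continue
            rollc = np.roll(Mc, 1, axis=comp) if grid.periodic3[comp] else \
                _edge_shift(Mc, comp)
            if grid.periodic3[ax]:
                corner_lo = 0.25 * (Mc + rollc + np.roll(Mc, 1, axis=ax)
                                    + np.roll(rollc, 1, axis=ax))
                corner_hi = np.roll(corner_lo, -1, axis=ax)
            else:
                corner_lo = 0.25 * (Mc + rollc + _edge_shift(Mc, ax)
                                    + _edge_shift(rollc, ax))
                corner_hi = _edge_shift(corner_lo, ax, -1)
            # value at the low comp-face of each cell
            out[tuple(low_faces)] += (corner_hi - corner_lo) / dx

    if grid.periodic3[comp]:
        first = [slice(None)] * 3
        last = [slice(None)] * 3
        first[comp] = 0
        last[comp] = -1
        out[tuple(last)] = out[tuple(first)]
    return out


def _edge_shift(a: np.ndarray, axis: int, direction: int = 1) -> np.ndarray:
    """np.roll with edge replication instead of wrap (non-periodic axes)."""
    out = np.roll(a, direction, axis=axis)
    sl = [slice(None)] * a.ndim
    if direction == 1:
        sl[axis] = 0
        src = [slice(None)] * a.ndim
        src[axis] = 0
        out[tuple(sl)] = a[tuple(src)]
    else:
        sl[axis] = -1
        src = [slice(None)] * a.ndim
        src[axis] = -1
        out[tuple(sl)] = a[tuple(src)]
    return out


def elastic_force(btilde: SymTensorField, alpha, props: SolidProps,
                  rho: float = 1.0) -> list[np.ndarray]:
    """Elastic acceleration (1/rho) div( G alpha^(1-beta) dev B~ ) at the
    velocity faces, in conservative flux form; identically zero wherever
    alpha = 0 (and wherever B~ is the unit reset, since dev I = 0)."""
    grid = btilde.grid
    a = alpha.data if isinstance(alpha, ScalarField) else np.asarray(alpha)
    w = props.G * np.maximum(a, 0.0) ** (1.0 - props.beta) / rho
    tr3 = (btilde.data[0] + btilde.data[1] + btilde.data[2]) / 3.0
    M = np.empty_like(btilde.data)
    for i in range(3):
        M[i] = w * (btilde.data[i] - tr3)
    for i in range(3, 6):
        M[i] = w * btilde.data[i]
    return [_face_div_sym(M, grid, comp) for comp in range(3)]
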