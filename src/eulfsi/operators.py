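"""Discrete operators shared by the solver modules.

All operators assume the uniform MAC arrangement of :mod:`eulfsi.grid`:
second-order central differences in the interior, one-sided stencils at
non-periodic boundaries, and a staggered divergence/gradient pair that is an
exact discrete adjoint so the pressure projection is idempotent.
"""
from __future__ import annotations

import numpy as np

from .grid import (BoundarySpec, CartesianGrid, ScalarField, SymTensorField,
                   VectorField)

__all__ = [
    "gradient",
    "divergence",
    "face_gradient",
    "velocity_gradient",
    "strain_rate",
    "deviatoric",
    "apply_bc",
    "cell_centered_velocity",
    "pad_scalar",
]


def _roll(a, shift, axis):
    return np.roll(a, shift, axis=axis)


def pad_scalar(data: np.ndarray, grid: CartesianGrid, width: int = 1,
               mode_per_axis=None, values=None) -> np.ndarray:
    """Ghost-pad a cell-centered array.

    ``mode_per_axis``: per axis a pair (lo, hi) of 'periodic' |
    'zero-gradient' | 'fixed' | 'reflect-odd'.  'fixed' sets the ghost so the
    linearly interpolated face value equals ``values[(axis, side)]``.
    """
    out = data
    for a in range(3):
        if mode_per_axis is None:
            modes = ("periodic", "periodic") if grid.periodic3[a] else \
                ("zero-gradient", "zero-gradient")
        else:
            modes = mode_per_axis[a]
        pads = [(0, 0)] * out.ndim
        pads[a] = (width, width)
        if modes == ("periodic", "periodic"):
            out = np.pad(out, pads, mode="wrap")
            continue
        out = np.pad(out, pads, mode="edge")
        for side, mode in enumerate(modes):
            if mode == "zero-gradient":
                continue
            sl = [slice(None)] * out.ndim
            for w in range(1, width + 1):
                ghost = width - w if side == 0 else out.shape[a] - width - 1 + w
                inner = width + w - 1 if side == 0 else \
                    out.shape[a] - width - w
                sl_g = list(sl)
                sl_i = list(sl)
                sl_g[a] = ghost
                sl_i[a] = inner
                if mode == "fixed":
                    v = 0.0 if values is None else values.get((a, side), 0.0)
                    out[tuple(sl_g)] = 2.0 * v - out[tuple(sl_i)]
                elif mode == "reflect-odd":
                    out[tuple(sl_g)] = -out[tuple(sl_i)]
                else:
                    raise ValueError(f"unknown pad mode {mode!r}")
    return out


def _central_deriv(data, grid, axis):
    """Cell-centered d/dx_axis: central interior, one-sided second order at
    non-periodic boundaries."""
    dx = grid.dx
    if grid.shape3[axis] == 1:
        return np.zeros_like(data)
    if grid.periodic3[axis]:
        return (_roll(data, -1, axis) - _roll(data, 1, axis)) / (2 * dx)
    d = np.empty_like(data)
    sl = [slice(None)] * 3

    def at(i):
        s = list(sl)
        s[axis] = i
        return tuple(s)

    d[at(slice(1, -1))] = (data[at(slice(2, None))]
                           - data[at(slice(None, -2))]) / (2 * dx)
    n = data.shape[axis]
    if n >= 3:
        d[at(0)] = (-3 * data[at(0)] + 4 * data[at(1)] - data[at(2)]) / (2 * dx)
        d[at(-1)] = (3 * data[at(-1)] - 4 * data[at(-2)] + data[at(-3)]) / (2 * dx)
    else:
        d[at(0)] = (data[at(1)] - data[at(0)]) / dx
        d[at(-1)] = (data[at(-1)] - data[at(-2)]) / dx
    return d


def gradient(field: ScalarField) -> list[np.ndarray]:
    """Cell-centered gradient of a scalar (one array per axis).

    Used for interface normals and diagnostics; the projection uses the
    staggered :func:`face_gradient`.
    """
    g = field.grid
    return [_central_deriv(field.data, g, a) for a in range(3)]


def face_gradient(p: np.ndarray, grid: CartesianGrid, axis: int) -> np.ndarray:
    """Pressure-gradient component on the faces normal to ``axis``.

    Exact adjoint of :func:`divergence`: interior face value
    (p[i] - p[i-1])/dx; boundary faces get 0 (their velocity is prescribed or
    periodic-synced by the caller).
    """
    dx = grid.dx
    out = np.zeros(grid.face_shape(axis))
    sl_in = [slice(None)] * 3
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_in[axis] = slice(1, -1)
    sl_lo[axis] = slice(None, -1)
    sl_hi[axis] = slice(1, None)
    out[tuple(sl_in)] = (p[tuple(sl_hi)] - p[tuple(sl_lo)]) / dx
    if grid.periodic3[axis]:
        first = [slice(None)] * 3
        last = [slice(None)] * 3
        pl = [slice(None)] * 3
        ph = [slice(None)] * 3
        first[axis] = 0
        last[axis] = -1
        pl[axis] = -1
        ph[axis] = 0
        out[tuple(first)] = (p[tuple(ph)] - p[tuple(pl)]) / dx
        out[tuple(last)] = out[tuple(first)]
    return out


def divergence(u: VectorField) -> ScalarField:
    """Cell divergence of a staggered vector field."""
    g = u.grid
    dx = g.dx
    div = np.zeros(g.shape3)
    for a in range(3):
        c = u.comps[a]
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[a] = slice(1, None)
        sl_lo[a] = slice(None, -1)
        div += (c[tuple(sl_hi)] - c[tuple(sl_lo)]) / dx
    return ScalarField(g, div, quantity="div")


def cell_centered_velocity(u: VectorField) -> list[np.ndarray]:
    """Average staggered components to cell centers."""
    out = []
    for a in range(3):
        c = u.comps[a]
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[a] = slice(1, None)
        sl_lo[a] = slice(None, -1)
        out.append(0.5 * (c[tuple(sl_hi)] + c[tuple(sl_lo)]))
    return out


def velocity_gradient(u: VectorField) -> np.ndarray:
    """Full cell-centered velocity-gradient tensor L[i, j] = du_i/dx_j,
    shape (3, 3) + grid.shape3."""
    g = u.grid
    ucc = cell_centered_velocity(u)
    L = np.zeros((3, 3) + g.shape3)
    for i in range(3):
        for j in range(3):
            L[i, j] = _central_deriv(ucc[i], g, j)
    return L


_SYM_IDX = {"xx": (0, 0), "yy": (1, 1), "zz": (2, 2),
            "xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}


def strain_rate(u: VectorField) -> SymTensorField:
    """Rate-of-strain tensor D = (L + L^T)/2 as a SymTensorField."""
    g = u.grid
    L = velocity_gradient(u)
    D = SymTensorField(g, quantity="D")
    for k, name in enumerate(SymTensorField._ORDER3):
        i, j = _SYM_IDX[name]
        D.data[k] = 0.5 * (L[i, j] + L[j, i])
    return D


def deviatoric(t: SymTensorField) -> SymTensorField:
    """Deviatoric part A' = A - tr(A)/3 I using the full 3-component trace
    (zz is carried explicitly in 2D)."""
    out = t.copy()
    tr3 = t.trace() / 3.0
    for i in range(3):
        out.data[i] = t.data[i] - tr3
    return out


def _wall_value(field, default):
    spec = field.spec
    if spec is None:
        return default
    return default


def apply_bc(field, spec: BoundarySpec | None = None):
    """Enforce boundary values on a field in place.

    For staggered vectors: periodic axes get their duplicated face synced,
    'fixed' normal components are written onto boundary faces, and wall-masked
    cells have all adjacent faces zeroed.  For scalars, wall-masked cells are
    set to the quantity's wall value (alpha -> 0); tensors get the unit tensor
    by default.  Ghost-layer construction for stencils is handled by
    :func:`pad_scalar` and the kernels.
    """
    spec = spec if spec is not None else field.spec
    g = field.grid
    if isinstance(field, VectorField):
        field.sync_periodic()
        if spec is not None:
            for a in range(g.ndim):
                for side in (0, 1):
                    bc = spec.get((a, side), field.quantity)
                    if bc.kind == "fixed":
                        val = bc.value
                        vn = val[a] if np.ndim(val) > 0 else val
                        sl = [slice(None)] * 3
                        sl[a] = 0 if side == 0 else -1
                        field.comps[a][tuple(sl)] = vn
        if g.wall_mask is not None:
            zero_wall_faces(field, g.wall_mask)
    elif isinstance(field, SymTensorField):
        if g.wall_mask is not None:
            wall = g.wall_mask
            for i in range(3):
                field.data[i][wall] = 1.0
            for i in range(3, 6):
                field.data[i][wall] = 0.0
    else:  # ScalarField
        if g.wall_mask is not None:
            field.data[g.wall_mask] = 0.0
    return field


def zero_wall_faces(u: VectorField, wall: np.ndarray):
    """Zero every face touching a wall cell (stair-step no-slip)."""
    for a in range(3):
        c = u.comps[a]
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[a] = slice(None, -1)
        hi[a] = slice(1, None)
        c[tuple(lo)][wall] = 0.0
        c[tuple(hi)][wall] = 0.0
    u.sync_periodic()
    return u
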