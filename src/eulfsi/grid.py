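"""Uniform Cartesian grids, staggered/cell-centered fields and boundary specs.

The solver describes both phases on a single fixed grid: scalars (volume
fraction, pressure) and tensors (left Cauchy-Green state, rate tensors) live at
cell centers, velocity components on the faces normal to their axis (MAC
arrangement).  Two-dimensional problems are carried internally as 3D arrays
with a single periodic cell along z, so every kernel has one code path; the
public API still reports ``ndim == 2`` and 4 tensor components in 2D.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "CartesianGrid",
    "ScalarField",
    "VectorField",
    "SymTensorField",
    "BC",
    "BoundarySpec",
    "sym_components",
]


def sym_components(ndim: int) -> tuple[str, ...]:
    """Component names of a symmetric tensor field.

    The zz component is carried explicitly in 2D (plane strain) so deviatoric
    parts use the true three-dimensional trace.
    """
    if ndim == 2:
        return ("xx", "yy", "zz", "xy")
    return ("xx", "yy", "zz", "xy", "xz", "yz")


class CartesianGrid:
    """Uniform structured grid, 2D or 3D.

    Parameters
    ----------
    shape : cell counts per axis (2 or 3 entries).
    lengths : domain lengths per axis, in units of the pipe diameter D.
    periodic : per-axis periodicity flags.
    wall_mask : optional boolean cell array marking wall/exterior cells
        (immutable after construction).

    Spacing must be identical on every axis to 1e-12: the WENO and PLIC
    kernels assume a uniform cube cell.
    """

    def __init__(self, shape, lengths, periodic=None, wall_mask=None):
        shape = tuple(int(n) for n in shape)
        lengths = tuple(float(L) for L in lengths)
        if len(shape) not in (2, 3) or len(lengths) != len(shape):
            raise ValueError("shape/lengths must have 2 or 3 matching entries")
        if any(n < 1 for n in shape):
            raise ValueError("cell counts must be positive")
        self.ndim = len(shape)
        if periodic is None:
            periodic = (False,) * self.ndim
        periodic = tuple(bool(p) for p in periodic)
        spacings = [L / n for L, n in zip(lengths, shape)]
        if max(spacings) - min(spacings) > 1e-12 * max(spacings):
            raise ValueError(
                f"grid spacing must be uniform across axes, got {spacings}"
            )
        self.shape = shape
        self.lengths = lengths
        self.periodic = periodic
        self.dx = spacings[0]
        # internal 3D view: nz=1, z periodic, Lz=dx
        if self.ndim == 2:
            self.shape3 = shape + (1,)
            self.lengths3 = lengths + (self.dx,)
            self.periodic3 = periodic + (True,)
        else:
            self.shape3 = shape
            self.lengths3 = lengths
            self.periodic3 = periodic
        if wall_mask is not None:
            wall_mask = np.asarray(wall_mask, dtype=bool)
            if wall_mask.shape == self.shape and self.ndim == 2:
                wall_mask = wall_mask[..., None]
            if wall_mask.shape != self.shape3:
                raise ValueError("wall_mask shape does not match grid")
            wall_mask = wall_mask.copy()
            wall_mask.setflags(write=False)
        self._wall_mask = wall_mask

    @property
    def wall_mask(self):
        return self._wall_mask

    @property
    def cell_volume(self) -> float:
        return self.dx ** self.ndim

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape3[axis]
        return (np.arange(n) + 0.5) * self.dx

    def axis_faces(self, axis: int) -> np.ndarray:
        return np.arange(self.shape3[axis] + 1) * self.dx

    def cell_centers(self):
        """Meshgrid (ij indexing) of cell-center coordinates, 3D arrays."""
        axes = [self.axis_centers(a) for a in range(3)]
        return np.meshgrid(*axes, indexing="ij")

    def face_shape(self, axis: int) -> tuple[int, ...]:
        s = list(self.shape3)
        s[axis] += 1
        return tuple(s)

    def fluid_mask(self) -> np.ndarray:
        if self._wall_mask is None:
            return np.ones(self.shape3, dtype=bool)
        return ~self._wall_mask

    def __repr__(self):
        return (f"CartesianGrid(shape={self.shape}, lengths={self.lengths}, "
                f"periodic={self.periodic}, dx={self.dx:.6g})")


@dataclass(frozen=True)
class BC:
    """Boundary condition for one quantity on one patch."""
    kind: str  # 'periodic' | 'fixed' | 'zero-gradient'
    value: Any = None

    def __post_init__(self):
        if self.kind not in ("periodic", "fixed", "zero-gradient"):
            raise ValueError(f"unknown BC kind {self.kind!r}")


_AX = "xyz"


class BoundarySpec:
    """Per-patch boundary descriptors.

    Patches are named faces of the box: for axis ``a`` the low side is patch
    ``(a, 0)`` and the high side ``(a, 1)``; conventional names (inlet, outlet,
    wall, top, ...) can be registered as aliases.  Periodic patches must come
    in matched pairs on the same axis.
    """

    def __init__(self, grid: CartesianGrid):
        self.grid = grid
        self._conds: dict[tuple[int, int, str], BC] = {}
        self._names: dict[str, tuple[int, int]] = {}
        for a in range(grid.ndim):
            self._names[f"{_AX[a]}lo"] = (a, 0)
            self._names[f"{_AX[a]}hi"] = (a, 1)

    def alias(self, name: str, axis: int, side: int) -> "BoundarySpec":
        self._names[name] = (axis, side)
        return self

    def set(self, patch, quantity: str, kind: str, value=None) -> "BoundarySpec":
        axis, side = self._names[patch] if isinstance(patch, str) else patch
        self._conds[(axis, side, quantity)] = BC(kind, value)
        return self

    def get(self, patch, quantity: str) -> BC:
        axis, side = self._names[patch] if isinstance(patch, str) else patch
        key = (axis, side, quantity)
        if key in self._conds:
            return self._conds[key]
        if self.grid.periodic3[axis]:
            return BC("periodic")
        raise KeyError(
            f"no boundary condition for quantity {quantity!r} on patch "
            f"axis={axis} side={side}; configuration incomplete"
        )

    def validate(self, quantities=("u", "p_rgh", "alpha", "btilde")):
        """Check completeness and matched periodic pairs."""
        for a in range(self.grid.ndim):
            for q in quantities:
                lo = self.get((a, 0), q)
                hi = self.get((a, 1), q)
                if (lo.kind == "periodic") != (hi.kind == "periodic"):
                    raise ValueError(
                        f"periodic patches must pair up on axis {a} for {q!r}"
                    )
        return self


class _Field:
    quantity = "scalar"

    def __init__(self, grid: CartesianGrid, spec: BoundarySpec | None = None):
        self.grid = grid
        self.spec = spec

    def check_finite(self):
        for a in self.arrays():
            if not np.isfinite(a).all():
                raise FloatingPointError(
                    f"{type(self).__name__} contains non-finite values"
                )
        return self


class ScalarField(_Field):
    """Cell-centered scalar; ``data`` has the internal 3D shape."""

    def __init__(self, grid, data=None, spec=None, quantity="scalar"):
        super().__init__(grid, spec)
        self.quantity = quantity
        if data is None:
            data = np.zeros(grid.shape3)
        else:
            data = np.asarray(data, dtype=float)
            if data.shape == grid.shape and grid.ndim == 2:
                data = data[..., None]
            if data.shape != grid.shape3:
                raise ValueError("data shape does not match grid")
        self.data = data

    def arrays(self):
        return (self.data,)

    def view2d(self):
        return self.data[..., 0] if self.grid.ndim == 2 else self.data

    def copy(self):
        return ScalarField(self.grid, self.data.copy(), self.spec, self.quantity)


class VectorField(_Field):
    """Staggered (MAC) velocity-like field: component d lives on d-faces."""

    def __init__(self, grid, comps=None, spec=None, quantity="u"):
        super().__init__(grid, spec)
        self.quantity = quantity
        if comps is None:
            comps = [np.zeros(grid.face_shape(a)) for a in range(3)]
        else:
            comps = [np.asarray(c, dtype=float) for c in comps]
            if len(comps) == 2 and grid.ndim == 2:
                comps = [c[..., None] for c in comps]
                comps.append(np.zeros(grid.face_shape(2)))
            for a, c in enumerate(comps):
                if c.shape != grid.face_shape(a):
                    raise ValueError(f"component {a} has wrong face shape")
        self.comps = list(comps)

    def arrays(self):
        return tuple(self.comps)

    def copy(self):
        return VectorField(self.grid, [c.copy() for c in self.comps],
                           self.spec, self.quantity)

    def sync_periodic(self):
        """Keep the duplicated face of periodic axes consistent."""
        for a in range(3):
            if self.grid.periodic3[a]:
                c = self.comps[a]
                idx_last = [slice(None)] * 3
                idx_first = [slice(None)] * 3
                idx_last[a] = -1
                idx_first[a] = 0
                c[tuple(idx_last)] = c[tuple(idx_first)]
        return self


class SymTensorField(_Field):
    """Cell-centered symmetric tensor.

    Always stores the six 3D components internally; the public component list
    depends on grid dimension (4 in 2D: xx, yy, zz, xy).
    """

    _ORDER3 = ("xx", "yy", "zz", "xy", "xz", "yz")

    def __init__(self, grid, data=None, spec=None, quantity="btilde"):
        super().__init__(grid, spec)
        self.quantity = quantity
        if data is None:
            data = np.zeros((6,) + grid.shape3)
        else:
            data = np.asarray(data, dtype=float)
            if data.shape != (6,) + grid.shape3:
                raise ValueError("tensor data must be (6,)+grid.shape3")
        self.data = data

    @property
    def components(self) -> tuple[str, ...]:
        return sym_components(self.grid.ndim)

    def comp(self, name: str) -> np.ndarray:
        return self.data[self._ORDER3.index(name)]

    def arrays(self):
        return (self.data,)

    def copy(self):
        return SymTensorField(self.grid, self.data.copy(), self.spec,
                              self.quantity)

    def trace(self) -> np.ndarray:
        return self.data[0] + self.data[1] + self.data[2]

    @classmethod
    def identity(cls, grid, scale=1.0):
        t = cls(grid)
        s = np.broadcast_to(np.asarray(scale, dtype=float), grid.shape3)
        for i in range(3):
            t.data[i] = s
        return t
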