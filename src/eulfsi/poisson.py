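"""Constant-coefficient pressure Poisson solvers on the MAC grid.

Three strategies, picked automatically:

* fully periodic box without walls: FFT diagonalization;
* periodic axial direction with an x-invariant wall mask (straight pipes):
  FFT along x, prefactorized sparse solves on the masked cross-section;
* everything else (cavity, stenosis): one sparse LU over the fluid cells.

All solvers use the discrete 7-point Laplacian that is the exact composition
of the staggered divergence and face gradient, so one projection renders the
velocity field divergence-free to the solver tolerance (here: direct solves,
i.e. round-off).
"""
from __future__ import annotations

import numpy as np
import scipy.fft
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .grid import CartesianGrid

__all__ = ["build_poisson", "PoissonSolver"]


class PoissonSolver:
    def solve(self, rhs: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _FFTPeriodic(PoissonSolver):
    """All active axes periodic, no wall mask."""

    def __init__(self, grid: CartesianGrid):
        self.grid = grid
        dx2 = grid.dx ** 2
        eigs = 0.0
        shape = grid.shape3
        for ax in range(3):
            n = shape[ax]
            k = np.arange(n)
            lam = (2.0 * np.cos(2.0 * np.pi * k / n) - 2.0) / dx2
            sh = [1, 1, 1]
            sh[ax] = n
            eigs = eigs + lam.reshape(sh)
        self._eigs = eigs

    def solve(self, rhs):
        rhat = scipy.fft.fftn(rhs)
        with np.errstate(divide="ignore", invalid="ignore"):
            phat = np.where(self._eigs != 0, rhat / self._eigs, 0.0)
        phat.flat[0] = 0.0
        return np.real(scipy.fft.ifftn(phat))


def _cross_section_matrix(grid: CartesianGrid, fluid2d: np.ndarray):
    """Neumann 5-point Laplacian on the fluid cells of the (y, z) section."""
    ny, nz = fluid2d.shape
    idx = -np.ones((ny, nz), dtype=int)
    cells = np.argwhere(fluid2d)
    idx[tuple(cells.T)] = np.arange(len(cells))
    n = len(cells)
    dx2 = grid.dx ** 2
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for d, period in ((0, grid.periodic3[1]), (1, grid.periodic3[2])):
        dims = (ny, nz)
        if dims[d] == 1:
            continue
        for s in (-1, 1):
            nb = cells.copy()
            nb[:, d] += s
            if period:
                nb[:, d] %= dims[d]
                valid = np.ones(len(cells), dtype=bool)
            else:
                valid = (nb[:, d] >= 0) & (nb[:, d] < dims[d])
            j = np.full(len(cells), -1)
            j[valid] = idx[tuple(nb[valid].T)]
            link = valid & (j >= 0)
            rows.extend(np.arange(n)[link])
            cols.extend(j[link])
            vals.extend(np.full(link.sum(), 1.0 / dx2))
            diag[link] -= 1.0 / dx2
    rows.extend(np.arange(n))
    cols.extend(np.arange(n))
    vals.extend(diag)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return A, cells, idx


class _FFTAxial(PoissonSolver):
    """Periodic axis 0, x-invariant wall mask, Neumann side walls."""

    def __init__(self, grid: CartesianGrid):
        self.grid = grid
        nx = grid.shape3[0]
        if grid.wall_mask is None:
            fluid2d = np.ones(grid.shape3[1:], dtype=bool)
        else:
            fluid2d = ~grid.wall_mask[0]
        self.fluid2d = fluid2d
        A, cells, idx = _cross_section_matrix(grid, fluid2d)
        self.cells = cells
        dx2 = grid.dx ** 2
        k = np.arange(nx // 2 + 1)
        lams = (2.0 * np.cos(2.0 * np.pi * k / nx) - 2.0) / dx2
        n = A.shape[0]
        self._lus = []
        for ki, lam in enumerate(lams):
            M = (A + lam * sp.identity(n, format="csr")).tolil()
            if ki == 0:
                # singular Neumann mode: pin the first fluid cell
                M.rows[0] = [0]
                M.data[0] = [1.0]
            self._lus.append(spla.splu(M.tocsc()))

    def solve(self, rhs):
        g = self.grid
        nx = g.shape3[0]
        rhat = scipy.fft.rfft(rhs, axis=0)
        sel = (slice(None),) + tuple(self.cells.T)  # (nmodes, ncells)
        rh = rhat[sel]
        rh[0] -= rh[0].mean()  # compatibility for the pinned mode
        out = np.zeros_like(rh)
        for ki, lu in enumerate(self._lus):
            b = np.column_stack([rh[ki].real, rh[ki].imag])
            if ki == 0:
                b[0] = 0.0  # pinned cell
            x = lu.solve(b)
            out[ki] = x[:, 0] + 1j * x[:, 1]
        phat = np.zeros(rhat.shape, dtype=complex)
        phat[sel] = out
        p = scipy.fft.irfft(phat, n=nx, axis=0)
        return p


class _Direct(PoissonSolver):
    """Sparse LU over the fluid cells; optional Dirichlet patches.

    ``dirichlet``: iterable of (axis, side) patches where the pressure
    increment vanishes on the boundary face.  Without any Dirichlet patch the
    Neumann problem is singular and the first fluid cell is pinned (the rhs
    mean is removed for compatibility).
    """

    def __init__(self, grid: CartesianGrid, dirichlet=()):
        self.grid = grid
        fluid = grid.fluid_mask()
        self.fluid = fluid
        cells = np.argwhere(fluid)
        self.cells = cells
        idx = -np.ones(grid.shape3, dtype=int)
        idx[tuple(cells.T)] = np.arange(len(cells))
        n = len(cells)
        dx2 = grid.dx ** 2
        diag = np.zeros(n)
        rows, cols, vals = [], [], []
        dir_set = set(tuple(d) for d in dirichlet)
        for ax in range(3):
            if grid.shape3[ax] == 1:
                continue
            for s in (-1, 1):
                nb = cells.copy()
                nb[:, ax] += s
                at_edge = (nb[:, ax] < 0) | (nb[:, ax] >= grid.shape3[ax])
                if grid.periodic3[ax]:
                    nb[:, ax] %= grid.shape3[ax]
                    at_edge[:] = False
                side = 0 if s < 0 else 1
                nb_clamped = nb.copy()
                nb_clamped[:, ax] = np.clip(nb_clamped[:, ax], 0,
                                            grid.shape3[ax] - 1)
                j = idx[tuple(nb_clamped.T)]
                interior_link = (~at_edge) & (j >= 0)
                rows.extend(np.arange(n)[interior_link])
                cols.extend(j[interior_link])
                vals.extend(np.full(int(interior_link.sum()), 1.0 / dx2))
                diag[interior_link] -= 1.0 / dx2
                if (ax, side) in dir_set:
                    # phi = 0 on the boundary face: ghost = -phi_c
                    dirich = at_edge
                    diag[dirich] -= 2.0 / dx2
        rows.extend(np.arange(n))
        cols.extend(np.arange(n))
        vals.extend(diag)
        A = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        self.singular = len(dir_set) == 0
        if self.singular:
            A = A.tolil()
            A.rows[0] = [0]
            A.data[0] = [1.0]
            A = A.tocsr()
        self._lu = spla.splu(A.tocsc())

    def solve(self, rhs):
        b = rhs[tuple(self.cells.T)].astype(float)
        if self.singular:
            b = b - b.mean()
            b[0] = 0.0
        x = self._lu.solve(b)
        out = np.zeros(self.grid.shape3)
        out[tuple(self.cells.T)] = x
        return out


def build_poisson(grid: CartesianGrid, dirichlet=()) -> PoissonSolver:
    """Pick the fastest applicable solver for this grid/BC combination."""
    active = [a for a in range(3) if grid.shape3[a] > 1]
    if not dirichlet and grid.wall_mask is None and \
            all(grid.periodic3[a] for a in active):
        return _FFTPeriodic(grid)
    if not dirichlet and grid.periodic3[0] and grid.shape3[0] > 1 and \
            not any(grid.periodic3[a] for a in (1, 2) if grid.shape3[a] > 1):
        mask_ok = grid.wall_mask is None or \
            bool(np.all(grid.wall_mask == grid.wall_mask[0][None]))
        if mask_ok:
            return _FFTAxial(grid)
    return _Direct(grid, dirichlet=dirichlet)
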