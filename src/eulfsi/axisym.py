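"""Axisymmetric reduction of the forced pipe flow.

For the pure-fluid Hagen-Poiseuille verification the full 3D stair-step pipe
is unnecessary: the axial momentum equation reduces to radial diffusion

    du/dt = nu (1/r) d/dr ( r du/dr ) + S,   u(R) = 0,

with the uniform forcing S adjusted every step to hold the bulk velocity at
its target.  The cylindrical finite-volume operator below is exact for
quadratic profiles (including the one-sided quadratic wall gradient), and
the bulk-velocity quadrature carries the Euler-Maclaurin end correction, so
the discrete steady state is the analytic parabola to solver tolerance.

Nondimensionalization: lengths in pipe diameters (R = 1/2), velocities in
U = 2 ubar, so nu = 1/Re_U with Re_U = 2 Re and the target bulk velocity is
ubar/U = 0.5.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

__all__ = ["AxisymmetricPipeFlow", "poiseuille_profile", "l2_error"]


def poiseuille_profile(y, mean=0.5):
    """Analytic axial velocity along a diameter, y in [0, 1]:
    u(y) = 8 ubar y (1 - y)."""
    y = np.asarray(y, float)
    return 8.0 * mean * y * (1.0 - y)


def l2_error(u, u_ref):
    """L2 norm (1/N sum (u_i - u_ref_i)^2)^(1/2)."""
    u = np.asarray(u, float)
    u_ref = np.asarray(u_ref, float)
    return float(np.sqrt(np.mean((u - u_ref) ** 2)))


@dataclass
class AxisymSteadyResult:
    u: np.ndarray          # radial profile at cell centers
    r: np.ndarray
    S: float               # steady uniform forcing (pressure gradient)
    bulk: float            # corrected-quadrature bulk velocity
    l2: float              # L2 error along the diameter vs the parabola
    steps: int
    t: float


class AxisymmetricPipeFlow:
    """Forced laminar pipe flow in the (r) reduction.

    Parameters
    ----------
    n_radial : cells across the radius (64 -> 128 across the diameter).
    re : Reynolds number on the mean-velocity/diameter scale (paper value 50).
    co : Courant number used for the nominal time step.
    target_mean : dimensionless bulk velocity held by the controller (0.5).
    """

    def __init__(self, n_radial: int = 64, re: float = 50.0, co: float = 0.1,
                 target_mean: float = 0.5):
        self.nr = int(n_radial)
        self.re = float(re)
        self.nu = 1.0 / (2.0 * re)   # U = 2 ubar scale
        self.co = float(co)
        self.target = float(target_mean)
        self.R = 0.5
        self.dr = self.R / self.nr
        self.r = (np.arange(self.nr) + 0.5) * self.dr
        self.u = np.zeros(self.nr)
        self.S = 0.0
        self.t = 0.0
        self.step_count = 0

    # ---------------------------------------------------------- operators
    def _matrix(self, dt):
        """Banded (I - dt nu L) with the quadratic wall-gradient closure."""
        nr, dr, r = self.nr, self.dr, self.r
        lam = dt * self.nu / dr ** 2
        ab = np.zeros((3, nr))
        rp = r + 0.5 * dr   # r_{j+1/2}
        rm = r - 0.5 * dr
        for j in range(nr):
            d = 0.0
            if j > 0:
                w = lam * rm[j] / r[j]
                ab[2, j - 1] = -w      # sub-diagonal (column j-1)
                d += w
            if j < nr - 1:
                w = lam * rp[j] / r[j]
                ab[0, j + 1] = -w      # super-diagonal
                d += w
            ab[1, j] = 1.0 + d
        # wall flux for the last cell: r_R u'(R), u'(R) exact for quadratics:
        # u'(R) = -(9 u_{n-1} - u_{n-2}) / (3 dr)
        j = nr - 1
        coef = dt * self.nu * self.R / (r[j] * dr * 3.0 * dr)
        ab[1, j] += 9.0 * coef
        ab[2, j - 1] += -coef
        return ab

    def _apply_matrix(self, dt, u):
        """(I - dt nu L) u, for residual checks."""
        nr, dr, r = self.nr, self.dr, self.r
        lam = dt * self.nu / dr ** 2
        out = u.copy()
        rp = r + 0.5 * dr
        rm = r - 0.5 * dr
        for j in range(nr):
            acc = 0.0
            if j > 0:
                acc += lam * rm[j] / r[j] * (u[j] - u[j - 1])
            if j < nr - 1:
                acc -= lam * rp[j] / r[j] * (u[j + 1] - u[j])
            out[j] += acc
        j = nr - 1
        coef = dt * self.nu * self.R / (r[j] * dr)
        out[j] += coef * (9.0 * u[j] - u[j - 1]) / (3.0 * dr)
        return out

    # --------------------------------------------------------- quadrature
    def bulk_velocity(self, u=None) -> float:
        """Bulk (cross-section mean) velocity with the Euler-Maclaurin end
        correction, exact for the quartic integrand of a parabolic profile."""
        if u is None:
            u = self.u
        r, dr, R = self.r, self.dr, self.R
        mid = float(np.sum(u * r) * dr)
        # f(r) = u r; f'(0) = u(0), f'(R) = R u'(R)
        u0 = (9.0 * u[0] - u[1]) / 8.0
        duR = -(9.0 * u[-1] - u[-2]) / (3.0 * dr)
        corr = dr ** 2 / 24.0 * (R * duR - u0)
        return 2.0 / R ** 2 * (mid + corr)

    # -------------------------------------------------------------- march
    def advance(self, dt):
        rhs = self.u + dt * self.S
        ab = self._matrix(dt)
        self.u = solve_banded((1, 1), ab, rhs)
        bulk = self.bulk_velocity()
        dS = (self.target - bulk) / dt
        self.u += dS * dt
        self.S += dS
        self.t += dt
        self.step_count += 1

    def nominal_dt(self):
        umax = max(float(np.max(np.abs(self.u))), 2.0 * self.target)
        return self.co * self.dr / umax

    def run_to_steady(self, tol: float = 1e-10, max_steps: int = 500_000
                      ) -> AxisymSteadyResult:
        """March until ||du/dt||_inf < tol (controller included)."""
        dt = self.nominal_dt()
        for _ in range(max_steps):
            prev = self.u.copy()
            self.advance(dt)
            if np.max(np.abs(self.u - prev)) / dt < tol:
                break
        return AxisymSteadyResult(
            u=self.u.copy(), r=self.r.copy(), S=float(self.S),
            bulk=self.bulk_velocity(), l2=self.l2_vs_analytic(),
            steps=self.step_count, t=self.t)

    # ------------------------------------------------------------ metrics
    def diameter_profile(self):
        """(y, u) samples along a diameter (mirrored radial profile)."""
        y = np.concatenate([0.5 - self.r[::-1], 0.5 + self.r])
        u = np.concatenate([self.u[::-1], self.u])
        return y, u

    def l2_vs_analytic(self) -> float:
        y, u = self.diameter_profile()
        return l2_error(u, poiseuille_profile(y, self.target))

    @property
    def analytic_forcing(self) -> float:
        """Steady Poiseuille gradient: S* = 16 / Re_U (= 32 nu ubar* / D*^2)."""
        return 16.0 / (2.0 * self.re)
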