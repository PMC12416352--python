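"""Deformation metrics of the transported particle.

All metrics are computed from the volume-fraction field and its alpha = 0.5
isosurface: centroid and centroid velocity (alpha-weighted means), the
orientation vector and angle psi from the gyration tensor of surface points,
tube-cross-section ellipse fits in the co-rotating local frame
(zeta, eta, xi), bending angles from the ellipse centers, and the aspect
ratios of the parallel-projected inner/outer outlines.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from skimage import measure

from .grid import CartesianGrid, ScalarField, VectorField
from .operators import cell_centered_velocity

log = logging.getLogger(__name__)

__all__ = [
    "Isosurface", "LocalFrame", "EllipseFit", "ShapeMetrics",
    "isosurface", "centroid", "centroid_velocity", "orientation",
    "local_frame", "cross_section_ellipses", "bending_angles",
    "projected_circle_ratios", "moving_average", "spectrum",
]


@dataclass
class Isosurface:
    """Triangulated alpha = level surface (vertices in domain coordinates)."""
    verts: np.ndarray
    faces: np.ndarray
    level: float = 0.5

    def euler_characteristic(self) -> int:
        edges = set()
        for tri in self.faces:
            for a, b in ((0, 1), (1, 2), (2, 0)):
                e = (min(tri[a], tri[b]), max(tri[a], tri[b]))
                edges.add(e)
        return int(len(self.verts) - len(edges) + len(self.faces))


@dataclass
class LocalFrame:
    """Right-handed orthonormal frame (zeta, eta, xi) at the centroid.

    xi is the orientation vector n; zeta is the initial z-axis
    re-orthonormalized against xi; eta = xi x zeta.
    """
    zeta: np.ndarray
    eta: np.ndarray
    xi: np.ndarray
    origin: np.ndarray

    def check(self, tol=1e-12):
        M = np.stack([self.zeta, self.eta, self.xi])
        if not np.allclose(M @ M.T, np.eye(3), atol=tol):
            raise ValueError("local frame is not orthonormal")
        if np.linalg.det(M) < 0:
            raise ValueError("local frame is not right-handed")
        return self


@dataclass
class EllipseFit:
    center: np.ndarray      # in-plane 2D coordinates
    h: float                # semi-axis along theta direction
    w: float                # semi-axis across
    theta: float            # radians
    rms: float
    center3: np.ndarray | None = None

    @property
    def aspect_ratio(self) -> float:
        hi = max(abs(self.h), abs(self.w))
        lo = min(abs(self.h), abs(self.w))
        return lo / hi


@dataclass
class ShapeMetrics:
    """One row of the per-snapshot metric series."""
    time: float
    centroid: np.ndarray
    centroid_velocity: np.ndarray
    psi_deg: float
    aspect_forward: float | None = None
    aspect_back: float | None = None
    aspect_right: float | None = None
    aspect_left: float | None = None
    bend_meridian_deg: float | None = None
    bend_prime_vertical_deg: float | None = None
    projected_inner_ratio: float | None = None
    projected_outer_ratio: float | None = None
    degenerate_orientation: bool = False

    COLUMNS = ("time", "xc_x", "xc_y", "xc_z", "uc_x", "uc_y", "uc_z",
               "psi_deg", "aspect_forward", "aspect_back", "aspect_right",
               "aspect_left", "bend_meridian_deg", "bend_prime_vertical_deg",
               "projected_inner_ratio", "projected_outer_ratio")

    def row(self):
        return (self.time, *self.centroid, *self.centroid_velocity,
                self.psi_deg, self.aspect_forward, self.aspect_back,
                self.aspect_right, self.aspect_left, self.bend_meridian_deg,
                self.bend_prime_vertical_deg, self.projected_inner_ratio,
                self.projected_outer_ratio)


# ------------------------------------------------------------- extraction

def _unwrap_roll(a: np.ndarray, grid: CartesianGrid, axis: int) -> int:
    """Cells to roll so the solid is contiguous along a periodic axis."""
    other = tuple(x for x in range(3) if x != axis)
    present = np.any(a > 1e-9, axis=other)
    n = len(present)
    if not (present[0] and present[-1]) or present.all():
        return 0
    gaps = np.where(~present)[0]
    return int(n - (gaps[-1] + 1))


def isosurface(alpha, grid: CartesianGrid | None = None, level: float = 0.5
               ) -> Isosurface:
    """Marching-cubes triangulation of the cell-centered alpha field.

    Periodic axes are unwrapped (the solid made contiguous) before
    extraction; vertex coordinates are returned in the unrolled continuous
    frame, which is what the metrics need.
    """
    if isinstance(alpha, ScalarField):
        grid = alpha.grid
        a = alpha.data
    else:
        a = np.asarray(alpha)
    dx = grid.dx
    shifts = [0, 0, 0]
    for ax in range(3):
        if grid.periodic3[ax] and grid.shape3[ax] > 1:
            s = _unwrap_roll(a, grid, ax)
            if s:
                a = np.roll(a, s, axis=ax)
                shifts[ax] = s
    verts, faces, _, _ = measure.marching_cubes(a, level=level,
                                                spacing=(dx, dx, dx))
    verts = verts + 0.5 * dx  # cell centers sit at (i + 1/2) dx
    for ax in range(3):
        if shifts[ax]:
            verts[:, ax] -= shifts[ax] * dx
    return Isosurface(verts, faces, level)


def contour2d(alpha, grid: CartesianGrid | None = None, level: float = 0.5):
    """alpha = level isolines of a 2D field (list of (N, 2) arrays)."""
    if isinstance(alpha, ScalarField):
        grid = alpha.grid
        a = alpha.view2d()
    else:
        a = np.asarray(alpha)
        if a.ndim == 3:
            a = a[..., 0]
    cs = measure.find_contours(a, level)
    return [(c + 0.5) * grid.dx for c in cs]


# ---------------------------------------------------------------- moments

def centroid(alpha, grid: CartesianGrid | None = None) -> np.ndarray:
    """Volume-fraction weighted centroid, with periodic axes unwrapped so a
    particle crossing the seam averages correctly."""
    if isinstance(alpha, ScalarField):
        grid = alpha.grid
        a = alpha.data
    else:
        a = np.asarray(alpha)
    tot = a.sum()
    if tot <= 0:
        raise ValueError("empty solid: centroid undefined")
    dx = grid.dx
    out = np.zeros(3)
    for ax in range(3):
        s = _unwrap_roll(a, grid, ax) if grid.periodic3[ax] else 0
        ar = np.roll(a, s, axis=ax) if s else a
        coords = (np.arange(grid.shape3[ax]) + 0.5) * dx
        other = tuple(x for x in range(3) if x != ax)
        m = ar.sum(axis=other)
        c = float((m * coords).sum() / tot)
        if s:
            c = (c - s * dx) % grid.lengths3[ax]
        out[ax] = c
    return out


def match_frame(xc: np.ndarray, verts: np.ndarray, grid: CartesianGrid
                ) -> np.ndarray:
    """Shift a domain-wrapped centroid by whole periods so it sits in the
    same continuous frame as the (unrolled) isosurface vertices."""
    out = np.asarray(xc, float).copy()
    ref = verts.mean(axis=0)
    for ax in range(3):
        if grid.periodic3[ax]:
            L = grid.lengths3[ax]
            out[ax] -= L * np.round((out[ax] - ref[ax]) / L)
    return out


def centroid_velocity(alpha, u: VectorField,
                      grid: CartesianGrid | None = None) -> np.ndarray:
    if isinstance(alpha, ScalarField):
        grid = alpha.grid
        a = alpha.data
    else:
        a = np.asarray(alpha)
    tot = a.sum()
    if tot <= 0:
        raise ValueError("empty solid: centroid velocity undefined")
    ucc = cell_centered_velocity(u)
    return np.array([float((a * c).sum() / tot) for c in ucc])


def orientation(surface: Isosurface | np.ndarray, xc: np.ndarray,
                prev_n: np.ndarray | None = None, gap_tol: float = 1e-9):
    """Orientation vector and angle from the gyration tensor.

    n is the eigenvector of the smallest eigenvalue (sign fixed to a
    non-negative x-component); psi = arccos |n . x| in degrees.  A
    (near-)degenerate smallest pair is flagged and the previous n reused.
    """
    pts = surface.verts if isinstance(surface, Isosurface) else \
        np.asarray(surface)
    if len(pts) < 100:
        raise ValueError("orientation needs at least 100 surface points")
    d = pts - xc
    G = (d[:, :, None] * d[:, None, :]).mean(axis=0)
    evals, evecs = np.linalg.eigh(G)
    degenerate = (evals[1] - evals[0]) < gap_tol * max(1.0, evals[-1])
    if degenerate and prev_n is not None:
        n = np.asarray(prev_n, float)
    else:
        n = evecs[:, 0]
    if n[0] < 0:
        n = -n
    psi = math.degrees(math.acos(min(1.0, abs(float(n[0])))))
    return n, psi, bool(degenerate)


def local_frame(n: np.ndarray, initial_z=(0.0, 0.0, 1.0)) -> LocalFrame:
    """Co-rotating frame: xi = n, zeta = initial z orthonormalized against
    xi, eta = xi x zeta (right-handed)."""
    xi = np.asarray(n, float)
    xi = xi / np.linalg.norm(xi)
    z0 = np.asarray(initial_z, float)
    z0 = z0 / np.linalg.norm(z0)
    if abs(float(np.dot(xi, z0))) > 1.0 - 1e-9:
        raise ValueError("orientation parallel to the reference z-axis; "
                         "outside the rotation-about-z regime")
    zeta = z0 - np.dot(z0, xi) * xi
    zeta = zeta / np.linalg.norm(zeta)
    eta = np.cross(xi, zeta)
    return LocalFrame(zeta, eta, xi, origin=None)


# ------------------------------------------------------------ ellipse fits

def fit_ellipse(X: np.ndarray, Y: np.ndarray) -> EllipseFit:
    """Least-squares fit of ((X'c + Y's)/h)^2 + ((-X's + Y'c)/w)^2 = 1 with
    center offset (X' = X - X0 etc.)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    x0, y0 = X.mean(), Y.mean()
    dxv = X - x0
    dyv = Y - y0
    C = np.cov(np.stack([dxv, dyv]))
    evals, evecs = np.linalg.eigh(C)
    th0 = math.atan2(evecs[1, 1], evecs[0, 1])
    h0 = math.sqrt(max(2.0 * evals[1], 1e-12))
    w0 = math.sqrt(max(2.0 * evals[0], 1e-12))

    def resid(p):
        X0, Y0, th, h, w = p
        ct, st = math.cos(th), math.sin(th)
        A = (X - X0) * ct + (Y - Y0) * st
        B = -(X - X0) * st + (Y - Y0) * ct
        return (A / h) ** 2 + (B / w) ** 2 - 1.0

    sol = least_squares(resid, [x0, y0, th0, h0, w0], method="lm",
                        xtol=1e-15, ftol=1e-15, max_nfev=2000)
    X0, Y0, th, h, w = sol.x
    h, w = abs(h), abs(w)
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return EllipseFit(np.array([X0, Y0]), h, w, th % math.pi, rms)


def _plane_section(surface: Isosurface, origin: np.ndarray,
                   normal: np.ndarray) -> np.ndarray:
    """Intersection points of the triangle mesh with a plane (3D points)."""
    v = surface.verts
    d = (v - origin) @ normal
    pts = []
    tri = surface.faces
    dt = d[tri]
    for e0, e1 in ((0, 1), (1, 2), (2, 0)):
        a = dt[:, e0]
        b = dt[:, e1]
        crossing = (a * b) < 0
        if not np.any(crossing):
            continue
        t = a[crossing] / (a[crossing] - b[crossing])
        p0 = v[tri[crossing, e0]]
        p1 = v[tri[crossing, e1]]
        pts.append(p0 + t[:, None] * (p1 - p0))
    if not pts:
        return np.zeros((0, 3))
    return np.concatenate(pts, axis=0)


def cross_section_ellipses(surface: Isosurface, frame: LocalFrame,
                           xc: np.ndarray, min_points: int = 8
                           ) -> dict[str, EllipseFit | None]:
    """Ellipse fits of the four tube cross-sections.

    Both cutting planes contain the torus axis xi: the meridian plane
    span(xi, eta) yields the forward (+eta) / back (-eta) pair, the prime
    vertical span(xi, zeta) the right (+zeta) / left (-zeta) pair.  Each
    planar loop is fitted with the rotated-ellipse model; loops with fewer
    than ``min_points`` points are reported missing.
    """
    out: dict[str, EllipseFit | None] = {}
    planes = {
        ("forward", "back"): (frame.zeta, frame.eta),   # normal zeta
        ("right", "left"): (frame.eta, frame.zeta),     # normal eta
    }
    for (pos_name, neg_name), (normal, split_dir) in planes.items():
        pts = _plane_section(surface, xc, normal)
        if len(pts) == 0:
            out[pos_name] = None
            out[neg_name] = None
            continue
        rel = pts - xc
        split = rel @ split_dir
        A = rel @ split_dir          # in-plane coordinate 1 (radial)
        B = rel @ frame.xi           # in-plane coordinate 2 (axial)
        for name, sel in ((pos_name, split > 0), (neg_name, split < 0)):
            if int(sel.sum()) < min_points:
                out[name] = None
                continue
            fit = fit_ellipse(A[sel], B[sel])
            fit.center3 = xc + fit.center[0] * split_dir \
                + fit.center[1] * frame.xi
            out[name] = fit
    return out


def bending_angles(ellipses: dict[str, EllipseFit | None], xc: np.ndarray,
                   frame: LocalFrame) -> tuple[float | None, float | None]:
    """Bend of each opposite cross-section pair, in degrees.

    0 for collinear centers (unbent); the magnitude is 180 deg minus the
    angle subtended at the centroid; the sign is positive when the pair
    midpoint lies on the +xi side."""
    def pair(a, b):
        fa, fb = ellipses.get(a), ellipses.get(b)
        if fa is None or fb is None or fa.center3 is None:
            return None
        v1 = fa.center3 - xc
        v2 = fb.center3 - xc
        cosang = float(np.dot(v1, v2)
                       / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        ang = 180.0 - math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
        mid = 0.5 * (fa.center3 + fb.center3) - xc
        sign = 1.0 if float(np.dot(mid, frame.xi)) >= 0 else -1.0
        return sign * ang

    return pair("forward", "back"), pair("right", "left")


def projected_circle_ratios(surface: Isosurface, frame: LocalFrame,
                            xc: np.ndarray, bins: int = 72
                            ) -> tuple[float | None, float | None]:
    """Aspect ratios of the inner and outer outlines of the parallel
    projection onto the (zeta, eta) plane.

    Vertices are binned by polar angle about the projected centroid; the
    per-bin minimum and maximum radii trace the two outlines, each fitted
    with an ellipse.  The inner outline is reported missing when the
    projection has no resolved hole (empty bin or the minimum radii collapse
    toward the center, e.g. for a sphere)."""
    rel = surface.verts - xc
    a = rel @ frame.zeta
    b = rel @ frame.eta
    ang = np.arctan2(b, a)
    r = np.hypot(a, b)
    edges = np.linspace(-math.pi, math.pi, bins + 1)
    which = np.clip(np.digitize(ang, edges) - 1, 0, bins - 1)
    rmin = np.full(bins, np.inf)
    rmax = np.full(bins, -np.inf)
    np.minimum.at(rmin, which, r)
    np.maximum.at(rmax, which, r)
    centers = 0.5 * (edges[:-1] + edges[1:])
    valid = np.isfinite(rmax) & (rmax > 0)
    if valid.sum() < bins:
        inner_ok = False
    else:
        inner_ok = bool(np.median(rmin) > 0.3 * np.median(rmax))
    outer_pts = (rmax[valid] * np.cos(centers[valid]),
                 rmax[valid] * np.sin(centers[valid]))
    outer = fit_ellipse(*outer_pts).aspect_ratio if valid.sum() >= 8 else None
    inner = None
    if inner_ok:
        inner = fit_ellipse(rmin * np.cos(centers),
                            rmin * np.sin(centers)).aspect_ratio
    return inner, outer


# ------------------------------------------------------------- series utils

def moving_average(series, window: int):
    """Centered moving average with edge-truncated windows ('up to' window
    points)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    s = np.asarray(series, float)
    half = window // 2
    out = np.empty_like(s)
    n = len(s)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = s[lo:hi].mean()
    return out


def spectrum(series, dt: float):
    """Magnitude spectrum of the de-meaned series: (frequencies,
    amplitudes)."""
    s = np.asarray(series, float)
    s = s - s.mean()
    amp = np.abs(np.fft.rfft(s))
    freq = np.fft.rfftfreq(len(s), dt)
    return freq, amp
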