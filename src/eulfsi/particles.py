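"""Analytic particle constructors, rasterization and wall masks.

Shapes (torus, disk, sphere, ellipsoid) are defined by signed-distance-like
indicator functions in a local frame whose z' axis is the particle's
orientation vector n (angle psi0 to the x-axis, rotation about z).  Volume
fractions are cell averages of the indicator estimated by stratified
supersampling; surface areas use the closed forms (Thomsen's approximation
with p = 1.6075 for the ellipsoid), and ``match_area`` reproduces the
surface-area-matched family used in the stenotic embolization comparison.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .grid import CartesianGrid, ScalarField

__all__ = ["ParticleSpec", "rasterize", "surface_area", "match_area",
           "pipe_mask", "stenosis_mask", "THOMSEN_P"]

THOMSEN_P = 1.6075


@dataclass(frozen=True)
class ParticleSpec:
    """Shape + placement of one particle (lengths in pipe diameters, D=1).

    Parameters by shape: torus (r, R); disk (h = full height h_D, r = radius
    r_D); sphere (r_S); ellipsoid (a_E, b_E, c_E semi-axes, b along the
    local z').
    ``psi0_deg`` is the angle between the orientation vector n and the
    x-axis; the rotation is about z, so n = (cos psi, sin psi, 0).
    """
    shape: str
    params: dict = field(default_factory=dict)
    center: tuple = (0.0, 0.0, 0.0)
    psi0_deg: float = 0.0

    def __post_init__(self):
        p = self.params
        if self.shape == "torus":
            if not (p["R"] > p["r"] > 0):
                raise ValueError("torus requires R > r > 0")
        elif self.shape == "disk":
            if not (p["h"] > 0 and p["r"] > 0):
                raise ValueError("disk requires positive h, r")
        elif self.shape == "sphere":
            if not p["r"] > 0:
                raise ValueError("sphere requires positive r")
        elif self.shape == "ellipsoid":
            if not all(p[k] > 0 for k in ("a", "b", "c")):
                raise ValueError("ellipsoid requires positive semi-axes")
        else:
            raise ValueError(f"unknown shape {self.shape!r}")
        if not (0.0 <= self.psi0_deg <= 90.0):
            raise ValueError("psi0 must lie in [0, 90] degrees")

    @property
    def orientation(self) -> np.ndarray:
        psi = math.radians(self.psi0_deg)
        return np.array([math.cos(psi), math.sin(psi), 0.0])

    def bounding_radius(self) -> float:
        p = self.params
        if self.shape == "torus":
            return p["R"] + p["r"]
        if self.shape == "disk":
            return math.hypot(p["r"], p["h"])
        if self.shape == "sphere":
            return p["r"]
        return max(p["a"], p["b"], p["c"])


def _local_coords(spec: ParticleSpec, x, y, z):
    """Rotate global coordinates into the particle frame.

    Local z' is along n; local x' along the global z-axis; local y'
    completes the right-handed triad (all shapes here are bodies of
    revolution about z' except the ellipsoid, whose long axis b is z').
    """
    psi = math.radians(spec.psi0_deg)
    cx, cy, cz = spec.center
    X = x - cx
    Y = y - cy
    Z = z - cz
    # n = (cos psi, sin psi, 0); frame: e3 = n, e1 = z_hat, e2 = e3 x e1
    zp = X * math.cos(psi) + Y * math.sin(psi)
    xp = Z
    yp = -X * math.sin(psi) + Y * math.cos(psi)
    return xp, yp, zp


def _inside(spec: ParticleSpec, x, y, z):
    xp, yp, zp = _local_coords(spec, x, y, z)
    p = spec.params
    if spec.shape == "torus":
        rho = np.sqrt(xp * xp + yp * yp)
        d = np.sqrt((rho - p["R"]) ** 2 + zp * zp) - p["r"]
        return d < 0
    if spec.shape == "disk":
        rho = np.sqrt(xp * xp + yp * yp)
        return (rho < p["r"]) & (np.abs(zp) < 0.5 * p["h"])
    if spec.shape == "sphere":
        return xp * xp + yp * yp + zp * zp < p["r"] ** 2
    # ellipsoid: b along z', a along x', c along y'
    return (xp / p["a"]) ** 2 + (yp / p["c"]) ** 2 + (zp / p["b"]) ** 2 < 1.0


def rasterize(spec: ParticleSpec, grid: CartesianGrid, supersampling: int = 3,
              check_wall: bool = True) -> ScalarField:
    """Cell-averaged indicator of the particle: alpha = solid fraction per
    cell, estimated from supersampling^d stratified sub-samples.

    Cells whose center is farther from the particle than the bounding radius
    plus one cell diagonal are skipped (exactly 0 or handled by sampling).
    """
    s = int(supersampling)
    if s < 1:
        raise ValueError("supersampling must be >= 1")
    dx = grid.dx
    shape = grid.shape3
    alpha = np.zeros(shape)
    # candidate cells: bounding box of the particle; on periodic axes the
    # box may extend beyond the domain and is wrapped on scatter
    rb = spec.bounding_radius() + dx
    los, his = [], []
    for ax in range(3):
        n = shape[ax]
        if n == 1:
            los.append(0)
            his.append(1)
            continue
        lo = int(np.floor((spec.center[ax] - rb) / dx))
        hi = int(np.ceil((spec.center[ax] + rb) / dx)) + 1
        if grid.periodic3[ax]:
            if hi - lo >= n:
                lo, hi = 0, n
        else:
            lo = max(lo, 0)
            hi = min(hi, n)
        los.append(lo)
        his.append(hi)
    if any(lo >= hi for lo, hi in zip(los, his)):
        return ScalarField(grid, alpha, quantity="alpha")
    offs = (np.arange(s) + 0.5) / s
    axes = []
    for ax in range(3):
        base = (np.arange(los[ax], his[ax]))[:, None] * dx
        axes.append((base + offs[None, :] * dx).ravel())
    if grid.ndim == 2:
        axes[2] = np.array([0.5 * dx] * 1)
    X, Y, Z = np.meshgrid(axes[0], axes[1], axes[2], indexing="ij")
    inside = _inside(spec, X, Y, Z)
    nz_s = 1 if grid.ndim == 2 else s
    nx_c = his[0] - los[0]
    ny_c = his[1] - los[1]
    nz_c = his[2] - los[2]
    inside = inside.reshape(nx_c, s, ny_c, s, nz_c, nz_s)
    frac = inside.mean(axis=(1, 3, 5))
    idxs = [np.arange(los[ax], his[ax]) % shape[ax] for ax in range(3)]
    alpha[np.ix_(*idxs)] = frac
    if check_wall and grid.wall_mask is not None:
        if np.any((alpha > 0) & grid.wall_mask):
            raise ValueError("particle intersects the wall mask at t=0")
    return ScalarField(grid, alpha, quantity="alpha")


def surface_area(spec: ParticleSpec) -> float:
    """Closed-form surface area (Thomsen approximation for the ellipsoid)."""
    p = spec.params
    if spec.shape == "torus":
        return 4.0 * math.pi ** 2 * p["r"] * p["R"]
    if spec.shape == "disk":
        # cylinder of radius r and full height 2h: 2 pi r (r + 2h)... the
        # matched family uses height h_D and radius r_D with area
        # 2 pi r_D (r_D + h_D), i.e. h is the full height
        return 2.0 * math.pi * p["r"] * (p["r"] + p["h"])
    if spec.shape == "sphere":
        return 4.0 * math.pi * p["r"] ** 2
    pw = THOMSEN_P
    a, b, c = p["a"], p["b"], p["c"]
    return 4.0 * math.pi * (((a * b) ** pw + (a * c) ** pw
                             + (b * c) ** pw) / 3.0) ** (1.0 / pw)


def match_area(reference: ParticleSpec, target_shape: str,
               constraints: dict | None = None) -> ParticleSpec:
    """Construct a particle of ``target_shape`` with the same surface area
    as ``reference``.

    Conventions of the matched family: the disk radius is twice its height
    (r_D = 2 h_D); the ellipsoid long axis is fixed (b_E = 0.4 by default)
    with a_E = c_E solved from the Thomsen formula by a bracketed root
    solve.
    """
    constraints = constraints or {}
    A = surface_area(reference)
    center = reference.center
    psi = reference.psi0_deg
    if target_shape == "sphere":
        rs = math.sqrt(A / (4.0 * math.pi))
        return ParticleSpec("sphere", {"r": rs}, center, psi)
    if target_shape == "disk":
        ratio = constraints.get("radius_to_height", 2.0)
        # A = 2 pi r (r + h), r = ratio h  ->  A = 2 pi ratio (ratio+1) h^2
        h = math.sqrt(A / (2.0 * math.pi * ratio * (ratio + 1.0)))
        return ParticleSpec("disk", {"h": h, "r": ratio * h}, center, psi)
    if target_shape == "ellipsoid":
        b = constraints.get("long_axis", 0.4)

        def f(a):
            s = ParticleSpec("ellipsoid", {"a": a, "b": b, "c": a})
            return surface_area(s) - A

        lo, hi = 1e-4, 5.0
        if f(lo) * f(hi) > 0:
            raise ValueError("no surface-area match in bracket")
        a = brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)
        return ParticleSpec("ellipsoid", {"a": a, "b": b, "c": a}, center, psi)
    if target_shape == "torus":
        return replace(reference)
    raise ValueError(f"unknown target shape {target_shape!r}")


def pipe_mask(grid: CartesianGrid, radius: float = 0.5, axis: int = 0,
              center=None) -> np.ndarray:
    """Stair-step cylinder wall: cells whose centers lie outside the
    cylinder of given radius around the axis."""
    if center is None:
        center = [0.5 * grid.lengths3[a] for a in range(3) if a != axis]
    X = grid.cell_centers()
    tr = [a for a in range(3) if a != axis]
    r2 = (X[tr[0]] - center[0]) ** 2 + (X[tr[1]] - center[1]) ** 2
    return r2 > radius ** 2


def stenosis_mask(grid: CartesianGrid, length: float, inlet_radius: float,
                  throat_radius: float, axis: int = 0,
                  taper_fraction: float = 0.5) -> np.ndarray:
    """Axisymmetric stenotic pipe wall mask.

    Radius profile: inlet radius at both ends, throat at midpoint, smooth
    cosine taper over the central ``taper_fraction`` of the length.
    """
    if throat_radius > inlet_radius:
        raise ValueError("throat radius must not exceed inlet radius")
    import warnings
    if 2.0 * throat_radius / grid.dx < 8:
        warnings.warn("fewer than 8 cells across the stenosis throat",
                      RuntimeWarning, stacklevel=2)
    X = grid.cell_centers()
    x = X[axis]
    half_taper = 0.5 * taper_fraction * length
    mid = 0.5 * length
    s = np.clip((x - mid) / half_taper, -1.0, 1.0)
    radius = inlet_radius - (inlet_radius - throat_radius) * \
        0.5 * (1.0 + np.cos(math.pi * s))
    tr = [a for a in range(3) if a != axis]
    c = [0.5 * grid.lengths3[a] for a in tr]
    r2 = (X[tr[0]] - c[0]) ** 2 + (X[tr[1]] - c[1]) ** 2
    return r2 > radius ** 2


def stenosis_radius_profile(x, length, inlet_radius, throat_radius,
                            taper_fraction=0.5):
    """Radius of the stenotic pipe at axial position x (same profile as the
    mask)."""
    x = np.asarray(x, float)
    half_taper = 0.5 * taper_fraction * length
    mid = 0.5 * length
    s = np.clip((x - mid) / half_taper, -1.0, 1.0)
    return inlet_radius - (inlet_radius - throat_radius) * \
        0.5 * (1.0 + np.cos(math.pi * s))
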