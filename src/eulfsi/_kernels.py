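"""Numba-compiled hot loops: WENO3 upwind advection and the staggered
momentum right-hand side.

All kernels operate on ghost-padded inputs prepared by the callers (two ghost
layers per side), so boundary logic stays in numpy and the loops need no
modular arithmetic.  With nz == 1 (2D runs) the z-ghosts replicate the single
layer, every z-difference vanishes and the kernels reduce to 2D arithmetic.
"""
from __future__ import annotations

from numba import njit

_EPS = 1.0e-6  # WENO smoothness regularization


@njit(cache=True, fastmath=True)
def _weno3_point(fm2, fm1, f0, fp1, fp2, upos, dx):
    """Third-order WENO approximation of df/dx at the center node.

    Two candidate stencils; ``upos`` selects the upwind bias.
    """
    if upos:
        b0 = (fm2 - 2.0 * fm1 + f0) ** 2
        b1 = (fm1 - 2.0 * f0 + fp1) ** 2
        a0 = (1.0 / 3.0) / (_EPS + b0) ** 2
        a1 = (2.0 / 3.0) / (_EPS + b1) ** 2
        w0 = a0 / (a0 + a1)
        w1 = a1 / (a0 + a1)
        d0 = (fm2 - 4.0 * fm1 + 3.0 * f0) / (2.0 * dx)
        d1 = (fp1 - fm1) / (2.0 * dx)
        return w0 * d0 + w1 * d1
    else:
        b0 = (fp2 - 2.0 * fp1 + f0) ** 2
        b1 = (fp1 - 2.0 * f0 + fm1) ** 2
        a0 = (1.0 / 3.0) / (_EPS + b0) ** 2
        a1 = (2.0 / 3.0) / (_EPS + b1) ** 2
        w0 = a0 / (a0 + a1)
        w1 = a1 / (a0 + a1)
        d0 = (-fp2 + 4.0 * fp1 - 3.0 * f0) / (2.0 * dx)
        d1 = (fp1 - fm1) / (2.0 * dx)
        return w0 * d0 + w1 * d1


@njit(cache=True, fastmath=True)
def weno3_advect(fp, ux, uy, uz, dx, out):
    """out = -(u . grad f) with componentwise WENO3 upwinding.

    ``fp``: (nc, nx+4, ny+4, nz+4) ghost-padded scalars; ``ux, uy, uz``:
    (nx, ny, nz) cell-centered convecting velocity; ``out``: (nc, nx, ny, nz).
    """
    nc = fp.shape[0]
    nx = out.shape[1]
    ny = out.shape[2]
    nz = out.shape[3]
    for c in range(nc):
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    I = i + 2
                    J = j + 2
                    K = k + 2
                    a = ux[i, j, k]
                    b = uy[i, j, k]
                    w = uz[i, j, k]
                    adv = 0.0
                    if a != 0.0:
                        adv += a * _weno3_point(
                            fp[c, I - 2, J, K], fp[c, I - 1, J, K],
                            fp[c, I, J, K], fp[c, I + 1, J, K],
                            fp[c, I + 2, J, K], a > 0.0, dx)
                    if b != 0.0:
                        adv += b * _weno3_point(
                            fp[c, I, J - 2, K], fp[c, I, J - 1, K],
                            fp[c, I, J, K], fp[c, I, J + 1, K],
                            fp[c, I, J + 2, K], b > 0.0, dx)
                    if w != 0.0:
                        adv += w * _weno3_point(
                            fp[c, I, J, K - 2], fp[c, I, J, K - 1],
                            fp[c, I, J, K], fp[c, I, J, K + 1],
                            fp[c, I, J, K + 2], w > 0.0, dx)
                    out[c, i, j, k] = -adv
    return out


@njit(cache=True, fastmath=True)
def _minmod(a, b):
    if a * b <= 0.0:
        return 0.0
    if abs(a) < abs(b):
        return a
    return b


@njit(cache=True, fastmath=True)
def _muscl_face(fm1, f0, fp1, fp2, a):
    """MUSCL (minmod-limited) reconstruction of the face value between nodes
    0 and +1 for convecting velocity ``a``."""
    if a >= 0.0:
        return f0 + 0.5 * _minmod(f0 - fm1, fp1 - f0)
    return fp1 - 0.5 * _minmod(fp1 - f0, fp2 - fp1)


@njit(cache=True, fastmath=True)
def momentum_rhs(up, vp, wp, mup, dx, ru, rv, rw):
    """Advection + viscous RHS for the three staggered components.

    Inputs are ghost-padded with 2 layers: ``up`` has shape
    (nx+1+4, ny+4, nz+4) etc., ``mup`` (nx+4, ny+4, nz+4).  Outputs ``ru``
    (nx+1, ny, nz), ``rv`` (nx, ny+1, nz), ``rw`` (nx, ny, nz+1) receive
    d(u)/dt contributions:  -div(u u) + div(2 mu D) (trace part absorbed by
    the projection).  Conservative telescoping fluxes: on periodic boxes the
    advective + viscous momentum change sums to round-off.
    """
    nxf = ru.shape[0]
    ny = ru.shape[1]
    nz = ru.shape[2]
    nx = rv.shape[0]
    nyf = rv.shape[1]
    nzf = rw.shape[2]
    idx = 1.0 / dx

    # ---- u momentum: nodes I=0..nx (padded index I+2)
    for I in range(nxf):
        for j in range(ny):
            for k in range(nz):
                Ip = I + 2
                jp = j + 2
                kp = k + 2
                # x-fluxes at cell centers flanking the u node
                # center at cell I (between u nodes I and I+1): a = mean u
                aR = 0.5 * (up[Ip, jp, kp] + up[Ip + 1, jp, kp])
                aL = 0.5 * (up[Ip - 1, jp, kp] + up[Ip, jp, kp])
                fR = _muscl_face(up[Ip - 1, jp, kp], up[Ip, jp, kp],
                                 up[Ip + 1, jp, kp], up[Ip + 2, jp, kp], aR)
                fL = _muscl_face(up[Ip - 2, jp, kp], up[Ip - 1, jp, kp],
                                 up[Ip, jp, kp], up[Ip + 1, jp, kp], aL)
                adv = (aR * fR - aL * fL) * idx
                # y-fluxes at corners (I, j+-1/2)
                bT = 0.5 * (vp[Ip - 1, jp + 1, kp] + vp[Ip, jp + 1, kp])
                bB = 0.5 * (vp[Ip - 1, jp, kp] + vp[Ip, jp, kp])
                fT = _muscl_face(up[Ip, jp - 1, kp], up[Ip, jp, kp],
                                 up[Ip, jp + 1, kp], up[Ip, jp + 2, kp], bT)
                fB = _muscl_face(up[Ip, jp - 2, kp], up[Ip, jp - 1, kp],
                                 up[Ip, jp, kp], up[Ip, jp + 1, kp], bB)
                adv += (bT * fT - bB * fB) * idx
                # z-fluxes
                cT = 0.5 * (wp[Ip - 1, jp, kp + 1] + wp[Ip, jp, kp + 1])
                cB = 0.5 * (wp[Ip - 1, jp, kp] + wp[Ip, jp, kp])
                gT = _muscl_face(up[Ip, jp, kp - 1], up[Ip, jp, kp],
                                 up[Ip, jp, kp + 1], up[Ip, jp, kp + 2], cT)
                gB = _muscl_face(up[Ip, jp, kp - 2], up[Ip, jp, kp - 1],
                                 up[Ip, jp, kp], up[Ip, jp, kp + 1], cB)
                adv += (cT * gT - cB * gB) * idx

                # viscous: d/dx(2 mu du/dx) with mu at cell centers
                muR = mup[Ip, jp, kp]        # cell I (to the right of node I)
                muL = mup[Ip - 1, jp, kp]
                vis = 2.0 * idx * idx * (
                    muR * (up[Ip + 1, jp, kp] - up[Ip, jp, kp])
                    - muL * (up[Ip, jp, kp] - up[Ip - 1, jp, kp]))
                # d/dy(mu (du/dy + dv/dx)) with mu at xy-corners
                muT = 0.25 * (mup[Ip - 1, jp, kp] + mup[Ip, jp, kp]
                              + mup[Ip - 1, jp + 1, kp] + mup[Ip, jp + 1, kp])
                muB = 0.25 * (mup[Ip - 1, jp - 1, kp] + mup[Ip, jp - 1, kp]
                              + mup[Ip - 1, jp, kp] + mup[Ip, jp, kp])
                tT = (up[Ip, jp + 1, kp] - up[Ip, jp, kp]) * idx \
                    + (vp[Ip, jp + 1, kp] - vp[Ip - 1, jp + 1, kp]) * idx
                tB = (up[Ip, jp, kp] - up[Ip, jp - 1, kp]) * idx \
                    + (vp[Ip, jp, kp] - vp[Ip - 1, jp, kp]) * idx
                vis += (muT * tT - muB * tB) * idx
                # d/dz(mu (du/dz + dw/dx)) with mu at xz-corners
                muF = 0.25 * (mup[Ip - 1, jp, kp] + mup[Ip, jp, kp]
                              + mup[Ip - 1, jp, kp + 1] + mup[Ip, jp, kp + 1])
                muK = 0.25 * (mup[Ip - 1, jp, kp - 1] + mup[Ip, jp, kp - 1]
                              + mup[Ip - 1, jp, kp] + mup[Ip, jp, kp])
                sF = (up[Ip, jp, kp + 1] - up[Ip, jp, kp]) * idx \
                    + (wp[Ip, jp, kp + 1] - wp[Ip - 1, jp, kp + 1]) * idx
                sK = (up[Ip, jp, kp] - up[Ip, jp, kp - 1]) * idx \
                    + (wp[Ip, jp, kp] - wp[Ip - 1, jp, kp]) * idx
                vis += (muF * sF - muK * sK) * idx

                ru[I, j, k] = -adv + vis

    # ---- v momentum: nodes J=0..ny
    for i in range(nx):
        for J in range(nyf):
            for k in range(nz):
                ip = i + 2
                Jp = J + 2
                kp = k + 2
                aR = 0.5 * (up[ip + 1, Jp - 1, kp] + up[ip + 1, Jp, kp])
                aL = 0.5 * (up[ip, Jp - 1, kp] + up[ip, Jp, kp])
                fR = _muscl_face(vp[ip - 1, Jp, kp], vp[ip, Jp, kp],
                                 vp[ip + 1, Jp, kp], vp[ip + 2, Jp, kp], aR)
                fL = _muscl_face(vp[ip - 2, Jp, kp], vp[ip - 1, Jp, kp],
                                 vp[ip, Jp, kp], vp[ip + 1, Jp, kp], aL)
                adv = (aR * fR - aL * fL) * idx
                bT = 0.5 * (vp[ip, Jp, kp] + vp[ip, Jp + 1, kp])
                bB = 0.5 * (vp[ip, Jp - 1, kp] + vp[ip, Jp, kp])
                fT = _muscl_face(vp[ip, Jp - 1, kp], vp[ip, Jp, kp],
                                 vp[ip, Jp + 1, kp], vp[ip, Jp + 2, kp], bT)
                fB = _muscl_face(vp[ip, Jp - 2, kp], vp[ip, Jp - 1, kp],
                                 vp[ip, Jp, kp], vp[ip, Jp + 1, kp], bB)
                adv += (bT * fT - bB * fB) * idx
                cT = 0.5 * (wp[ip, Jp - 1, kp + 1] + wp[ip, Jp, kp + 1])
                cB = 0.5 * (wp[ip, Jp - 1, kp] + wp[ip, Jp, kp])
                gT = _muscl_face(vp[ip, Jp, kp - 1], vp[ip, Jp, kp],
                                 vp[ip, Jp, kp + 1], vp[ip, Jp, kp + 2], cT)
                gB = _muscl_face(vp[ip, Jp, kp - 2], vp[ip, Jp, kp - 1],
                                 vp[ip, Jp, kp], vp[ip, Jp, kp + 1], cB)
                adv += (cT * gT - cB * gB) * idx

                muT = mup[ip, Jp, kp]
                muB = mup[ip, Jp - 1, kp]
                vis = 2.0 * idx * idx * (
                    muT * (vp[ip, Jp + 1, kp] - vp[ip, Jp, kp])
                    - muB * (vp[ip, Jp, kp] - vp[ip, Jp - 1, kp]))
                muR = 0.25 * (mup[ip, Jp - 1, kp] + mup[ip + 1, Jp - 1, kp]
                              + mup[ip, Jp, kp] + mup[ip + 1, Jp, kp])
                muL = 0.25 * (mup[ip - 1, Jp - 1, kp] + mup[ip, Jp - 1, kp]
                              + mup[ip - 1, Jp, kp] + mup[ip, Jp, kp])
                tR = (vp[ip + 1, Jp, kp] - vp[ip, Jp, kp]) * idx \
                    + (up[ip + 1, Jp, kp] - up[ip + 1, Jp - 1, kp]) * idx
                tL = (vp[ip, Jp, kp] - vp[ip - 1, Jp, kp]) * idx \
                    + (up[ip, Jp, kp] - up[ip, Jp - 1, kp]) * idx
                vis += (muR * tR - muL * tL) * idx
                muF = 0.25 * (mup[ip, Jp - 1, kp] + mup[ip, Jp, kp]
                              + mup[ip, Jp - 1, kp + 1] + mup[ip, Jp, kp + 1])
                muK = 0.25 * (mup[ip, Jp - 1, kp - 1] + mup[ip, Jp, kp - 1]
                              + mup[ip, Jp - 1, kp] + mup[ip, Jp, kp])
                sF = (vp[ip, Jp, kp + 1] - vp[ip, Jp, kp]) * idx \
                    + (wp[ip, Jp, kp + 1] - wp[ip, Jp - 1, kp + 1]) * idx
                sK = (vp[ip, Jp, kp] - vp[ip, Jp, kp - 1]) * idx \
                    + (wp[ip, Jp, kp] - wp[ip, Jp - 1, kp]) * idx
                vis += (muF * sF - muK * sK) * idx

                rv[i, J, k] = -adv + vis

    # ---- w momentum: nodes K=0..nz
    for i in range(nx):
        for j in range(ny):
            for K in range(nzf):
                ip = i + 2
                jp = j + 2
                Kp = K + 2
                aR = 0.5 * (up[ip + 1, jp, Kp - 1] + up[ip + 1, jp, Kp])
                aL = 0.5 * (up[ip, jp, Kp - 1] + up[ip, jp, Kp])
                fR = _muscl_face(wp[ip - 1, jp, Kp], wp[ip, jp, Kp],
                                 wp[ip + 1, jp, Kp], wp[ip + 2, jp, Kp], aR)
                fL = _muscl_face(wp[ip - 2, jp, Kp], wp[ip - 1, jp, Kp],
                                 wp[ip, jp, Kp], wp[ip + 1, jp, Kp], aL)
                adv = (aR * fR - aL * fL) * idx
                bT = 0.5 * (vp[ip, jp + 1, Kp - 1] + vp[ip, jp + 1, Kp])
                bB = 0.5 * (vp[ip, jp, Kp - 1] + vp[ip, jp, Kp])
                fT = _muscl_face(wp[ip, jp - 1, Kp], wp[ip, jp, Kp],
                                 wp[ip, jp + 1, Kp], wp[ip, jp + 2, Kp], bT)
                fB = _muscl_face(wp[ip, jp - 2, Kp], wp[ip, jp - 1, Kp],
                                 wp[ip, jp, Kp], wp[ip, jp + 1, Kp], bB)
                adv += (bT * fT - bB * fB) * idx
                cT = 0.5 * (wp[ip, jp, Kp] + wp[ip, jp, Kp + 1])
                cB = 0.5 * (wp[ip, jp, Kp - 1] + wp[ip, jp, Kp])
                gT = _muscl_face(wp[ip, jp, Kp - 1], wp[ip, jp, Kp],
                                 wp[ip, jp, Kp + 1], wp[ip, jp, Kp + 2], cT)
                gB = _muscl_face(wp[ip, jp, Kp - 2], wp[ip, jp, Kp - 1],
                                 wp[ip, jp, Kp], wp[ip, jp, Kp + 1], cB)
                adv += (cT * gT - cB * gB) * idx

                muF = mup[ip, jp, Kp]
                muK = mup[ip, jp, Kp - 1]
                vis = 2.0 * idx * idx * (
                    muF * (wp[ip, jp, Kp + 1] - wp[ip, jp, Kp])
                    - muK * (wp[ip, jp, Kp] - wp[ip, jp, Kp - 1]))
                muR = 0.25 * (mup[ip, jp, Kp - 1] + mup[ip + 1, jp, Kp - 1]
                              + mup[ip, jp, Kp] + mup[ip + 1, jp, Kp])
                muL = 0.25 * (mup[ip - 1, jp, Kp - 1] + mup[ip, jp, Kp - 1]
                              + mup[ip - 1, jp, Kp] + mup[ip, jp, Kp])
                tR = (wp[ip + 1, jp, Kp] - wp[ip, jp, Kp]) * idx \
                    + (up[ip + 1, jp, Kp] - up[ip + 1, jp, Kp - 1]) * idx
                tL = (wp[ip, jp, Kp] - wp[ip - 1, jp, Kp]) * idx \
                    + (up[ip, jp, Kp] - up[ip, jp, Kp - 1]) * idx
                vis += (muR * tR - muL * tL) * idx
                muT = 0.25 * (mup[ip, jp, Kp - 1] + mup[ip, jp + 1, Kp - 1]
                              + mup[ip, jp, Kp] + mup[ip, jp + 1, Kp])
                muB = 0.25 * (mup[ip, jp - 1, Kp - 1] + mup[ip, jp, Kp - 1]
                              + mup[ip, jp - 1, Kp] + mup[ip, jp, Kp])
                sT = (wp[ip, jp + 1, Kp] - wp[ip, jp, Kp]) * idx \
                    + (vp[ip, jp + 1, Kp] - vp[ip, jp + 1, Kp - 1]) * idx
                sB = (wp[ip, jp, Kp] - wp[ip, jp - 1, Kp]) * idx \
                    + (vp[ip, jp, Kp] - vp[ip, jp, Kp - 1]) * idx
                vis += (muT * sT - muB * sB) * idx

                rw[i, j, K] = -adv + vis

    return ru


# --------------------------------------------------------- PLIC geometry

@njit(cache=True)
def _cut_below_scalar(m1, m2, m3, c):
    """Fraction of the unit cube with m . x <= c (m >= 0 componentwise).

    Case-wise closed form with the difference on the smallest coefficient
    taken analytically (c^3 - (c-m1)^3 = m1 (3c(c-m1) + m1^2)), so the
    evaluation stays cancellation-free even for nearly axis-aligned planes;
    this keeps plane positioning and donor-flux geometry consistent to
    round-off, which the bounded advection update relies on.
    """
    s = m1 + m2 + m3
    if s <= 0.0:
        return 1.0 if c >= 0.0 else 0.0
    if c <= 0.0:
        return 0.0
    if c >= s:
        return 1.0
    # sort ascending: a <= b <= d
    a = m1
    b = m2
    d = m3
    if a > b:
        a, b = b, a
    if b > d:
        b, d = d, b
    if a > b:
        a, b = b, a
    mirror = False
    if c > 0.5 * s:
        c = s - c
        mirror = True
    # now 0 < c <= s/2
    if c < a:
        v = c * c * c / (6.0 * a * b * d)
    elif c < b:
        v = (3.0 * c * (c - a) + a * a) / (6.0 * b * d)
    elif c < min(d, a + b):
        v = (3.0 * c * (c - a) + a * a) / (6.0 * b * d) \
            - (c - b) ** 3 / (6.0 * a * b * d)
    elif d < a + b:
        # c in [d, s/2]
        v = (3.0 * c * (c - a) + a * a) / (6.0 * b * d) \
            - (c - b) ** 3 / (6.0 * a * b * d) \
            - (c - d) ** 3 / (6.0 * a * b * d)
    else:
        # slab regime: c in [a + b, d)
        v = (2.0 * c - a - b) / (2.0 * d)
    if mirror:
        v = 1.0 - v
    if v < 0.0:
        v = 0.0
    if v > 1.0:
        v = 1.0
    return v


@njit(cache=True)
def solid_fraction_slab(n1, n2, n3, c, l1, l2, l3, h1, h2, h3):
    """Solid (n . x >= c) fraction of the sub-slab [l, h] of the unit cell,
    relative to the FULL cell volume."""
    w1 = h1 - l1
    w2 = h2 - l2
    w3 = h3 - l3
    vol = w1 * w2 * w3
    if vol <= 0.0:
        return 0.0
    m1 = n1 * w1
    m2 = n2 * w2
    m3 = n3 * w3
    cc = c - (n1 * l1 + n2 * l2 + n3 * l3)
    # solid m.t >= cc -> (-m).t <= -cc; reflect negatives
    a1 = -m1
    a2 = -m2
    a3 = -m3
    c2 = -cc
    if a1 < 0.0:
        c2 -= a1
        a1 = -a1
    if a2 < 0.0:
        c2 -= a2
        a2 = -a2
    if a3 < 0.0:
        c2 -= a3
        a3 = -a3
    return _cut_below_scalar(a1, a2, a3, c2) * vol


@njit(cache=True)
def plane_constants(normals, alphas, out):
    """Per-cell bisection for the PLIC plane constant (solid n.x >= c)."""
    N = normals.shape[0]
    for i in range(N):
        n1 = normals[i, 0]
        n2 = normals[i, 1]
        n3 = normals[i, 2]
        al = alphas[i]
        lo = min(n1, 0.0) + min(n2, 0.0) + min(n3, 0.0)
        hi = max(n1, 0.0) + max(n2, 0.0) + max(n3, 0.0)
        a = lo
        b = hi
        for _ in range(50):
            mid = 0.5 * (a + b)
            f = solid_fraction_slab(n1, n2, n3, mid,
                                    0.0, 0.0, 0.0, 1.0, 1.0, 1.0)
            if f > al:
                a = mid
            else:
                b = mid
        out[i] = 0.5 * (a + b)
    return out


@njit(cache=True)
def donor_fluxes(normals, consts, widths, axis, out):
    """Geometric donor-slab solid fractions for interface donor cells.

    widths: signed face Courant numbers (w > 0: slab [1-w, 1]; w < 0:
    slab [0, -w]); out receives the signed flux fraction."""
    N = normals.shape[0]
    for i in range(N):
        w = widths[i]
        if w == 0.0:
            out[i] = 0.0
            continue
        l1 = 0.0
        l2 = 0.0
        l3 = 0.0
        h1 = 1.0
        h2 = 1.0
        h3 = 1.0
        if w > 0.0:
            if axis == 0:
                l1 = 1.0 - w
            elif axis == 1:
                l2 = 1.0 - w
            else:
                l3 = 1.0 - w
        else:
            if axis == 0:
                h1 = -w
            elif axis == 1:
                h2 = -w
            else:
                h3 = -w
        f = solid_fraction_slab(normals[i, 0], normals[i, 1], normals[i, 2],
                                consts[i], l1, l2, l3, h1, h2, h3)
        out[i] = f if w > 0.0 else -f
    return out


@njit(cache=True)
def solid_fractions(normals, consts, lo, hi, out):
    """Vectorized solid_fraction_slab over rows."""
    for i in range(normals.shape[0]):
        out[i] = solid_fraction_slab(
            normals[i, 0], normals[i, 1], normals[i, 2], consts[i],
            lo[i, 0], lo[i, 1], lo[i, 2], hi[i, 0], hi[i, 1], hi[i, 2])
    return out
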