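"""Low-level geometry kernels (numba): internal-coordinate chain building,
dihedral measurement and superposition-free RMSD.

All angles are radians here; the public modules speak degrees.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def build_coords(parent, grand, ggrand, bond, angle, torsion, out):
    """Place atoms sequentially from internal coordinates (NeRF).

    Atoms 0..2 are seeded in a canonical frame: atom0 at the origin, atom1 on
    +x, atom2 in the xy-plane. Every later atom k is placed at bond length
    ``bond[k]`` from ``parent[k]``, bond angle ``angle[k]`` at the parent and
    dihedral ``torsion[k]`` measured over (atom, parent, grand, ggrand).
    """
    n = parent.shape[0]
    out[0, 0] = 0.0
    out[0, 1] = 0.0
    out[0, 2] = 0.0
    if n > 1:
        out[1, 0] = bond[1]
        out[1, 1] = 0.0
        out[1, 2] = 0.0
    if n > 2:
        # parent must be atom 1, grand atom 0
        out[2, 0] = out[1, 0] - bond[2] * np.cos(angle[2])
        out[2, 1] = bond[2] * np.sin(angle[2])
        out[2, 2] = 0.0
    for k in range(3, n):
        c = parent[k]
        b = grand[k]
        a = ggrand[k]
        bcx = out[c, 0] - out[b, 0]
        bcy = out[c, 1] - out[b, 1]
        bcz = out[c, 2] - out[b, 2]
        nb = np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
        bcx /= nb
        bcy /= nb
        bcz /= nb
        abx = out[b, 0] - out[a, 0]
        aby = out[b, 1] - out[a, 1]
        abz = out[b, 2] - out[a, 2]
        # normal to the (a,b,c) plane
        nx = aby * bcz - abz * bcy
        ny = abz * bcx - abx * bcz
        nz = abx * bcy - aby * bcx
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        nx /= nn
        ny /= nn
        nz /= nn
        # m completes the right-handed frame (bc, m, n)
        mx = ny * bcz - nz * bcy
        my = nz * bcx - nx * bcz
        mz = nx * bcy - ny * bcx
        bl = bond[k]
        th = angle[k]
        ta = torsion[k]
        d0 = -bl * np.cos(th)
        d1 = bl * np.sin(th) * np.cos(ta)
        d2 = bl * np.sin(th) * np.sin(ta)
        out[k, 0] = out[c, 0] + d0 * bcx + d1 * mx + d2 * nx
        out[k, 1] = out[c, 1] + d0 * bcy + d1 * my + d2 * ny
        out[k, 2] = out[c, 2] + d0 * bcz + d1 * mz + d2 * nz


def dihedral(p0, p1, p2, p3):
    """Signed dihedral (radians, IUPAC convention) for points or arrays (...,3)."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    c1 = np.cross(b1, b2)
    c2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(c1 * c2, axis=-1)
    y = np.sum(np.cross(c1, c2) * b2n, axis=-1)
    return np.arctan2(y, x)


def bond_angle(p0, p1, p2):
    """Angle at p1 (radians)."""
    u = p0 - p1
    v = p2 - p1
    cosang = np.sum(u * v, axis=-1) / (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


@njit(cache=True)
def _eig3_sym(a00, a01, a02, a11, a12, a22):
    """Eigenvalues of a symmetric 3x3 matrix, descending (trigonometric form)."""
    p1 = a01 * a01 + a02 * a02 + a12 * a12
    q = (a00 + a11 + a22) / 3.0
    if p1 < 1e-30:
        e0 = max(a00, max(a11, a22))
        e2 = min(a00, min(a11, a22))
        e1 = a00 + a11 + a22 - e0 - e2
        return e0, e1, e2
    p2 = (a00 - q) ** 2 + (a11 - q) ** 2 + (a22 - q) ** 2 + 2.0 * p1
    p = np.sqrt(p2 / 6.0)
    b00 = (a00 - q) / p
    b11 = (a11 - q) / p
    b22 = (a22 - q) / p
    b01 = a01 / p
    b02 = a02 / p
    b12 = a12 / p
    detb = (
        b00 * (b11 * b22 - b12 * b12)
        - b01 * (b01 * b22 - b12 * b02)
        + b02 * (b01 * b12 - b11 * b02)
    )
    r = detb / 2.0
    if r < -1.0:
        r = -1.0
    elif r > 1.0:
        r = 1.0
    phi = np.arccos(r) / 3.0
    e0 = q + 2.0 * p * np.cos(phi)
    e2 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e1 = 3.0 * q - e0 - e2
    # Newton polish on the characteristic polynomial (restores the ~1e-15
    # relative accuracy the trigonometric form loses)
    tr = a00 + a11 + a22
    m2 = (a00 * a11 - a01 * a01) + (a00 * a22 - a02 * a02) + (a11 * a22 - a12 * a12)
    det = (a00 * (a11 * a22 - a12 * a12)
           - a01 * (a01 * a22 - a12 * a02)
           + a02 * (a01 * a12 - a11 * a02))
    out = np.empty(3)
    evs = (e0, e1, e2)
    for i in range(3):
        lam = evs[i]
        for _ in range(2):
            f = ((lam - tr) * lam + m2) * lam - det
            df = (3.0 * lam - 2.0 * tr) * lam + m2
            if df != 0.0:
                lam -= f / df
        out[i] = lam
    out.sort()
    return out[2], out[1], out[0]


@njit(cache=True)
def kabsch_rmsd(a, b):
    """Minimum RMSD between (n,3) coordinate sets after optimal superposition.

    Uses the covariance singular values (Kabsch with reflection correction);
    no rotation matrix is formed.
    """
    n = a.shape[0]
    # center
    acx = 0.0
    acy = 0.0
    acz = 0.0
    bcx = 0.0
    bcy = 0.0
    bcz = 0.0
    for i in range(n):
        acx += a[i, 0]
        acy += a[i, 1]
        acz += a[i, 2]
        bcx += b[i, 0]
        bcy += b[i, 1]
        bcz += b[i, 2]
    acx /= n
    acy /= n
    acz /= n
    bcx /= n
    bcy /= n
    bcz /= n
    ga = 0.0
    gb = 0.0
    m = np.zeros((3, 3))
    for i in range(n):
        ax = a[i, 0] - acx
        ay = a[i, 1] - acy
        az = a[i, 2] - acz
        bx = b[i, 0] - bcx
        by = b[i, 1] - bcy
        bz = b[i, 2] - bcz
        ga += ax * ax + ay * ay + az * az
        gb += bx * bx + by * by + bz * bz
        m[0, 0] += ax * bx
        m[0, 1] += ax * by
        m[0, 2] += ax * bz
        m[1, 0] += ay * bx
        m[1, 1] += ay * by
        m[1, 2] += ay * bz
        m[2, 0] += az * bx
        m[2, 1] += az * by
        m[2, 2] += az * bz
    detm = (
        m[0, 0] * (m[1, 1] * m[2, 2] - m[1, 2] * m[2, 1])
        - m[0, 1] * (m[1, 0] * m[2, 2] - m[1, 2] * m[2, 0])
        + m[0, 2] * (m[1, 0] * m[2, 1] - m[1, 1] * m[2, 0])
    )
    # M^T M is symmetric; its eigenvalues are the squared singular values.
    k = m.T @ m
    e0, e1, e2 = _eig3_sym(k[0, 0], k[0, 1], k[0, 2], k[1, 1], k[1, 2], k[2, 2])
    s0 = np.sqrt(max(e0, 0.0))
    s1 = np.sqrt(max(e1, 0.0))
    s2 = np.sqrt(max(e2, 0.0))
    if detm < 0.0:
        s2 = -s2
    msd = (ga + gb - 2.0 * (s0 + s1 + s2)) / n
    if msd < 0.0:
        msd = 0.0
    return np.sqrt(msd)


@njit(cache=True)
def pairwise_rmsd_matrix(coords):
    """Condensed upper-triangle RMSD matrix for (m, n, 3) coordinate sets."""
    m = coords.shape[0]
    out = np.empty(m * (m - 1) // 2, dtype=np.float32)
    idx = 0
    for i in range(m):
        for j in range(i + 1, m):
            out[idx] = kabsch_rmsd(coords[i], coords[j])
            idx += 1
    return out
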