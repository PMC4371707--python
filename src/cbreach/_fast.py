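"""Numba-accelerated kernels for the simulation hot paths.

These kernels mirror the vectorized numpy implementations in
:mod:`cbreach.kinematics` and :mod:`cbreach.plant` exactly; they exist only
because the control loop evaluates small batches (9 poses) thousands of
times per reach, where Python/numpy dispatch overhead dominates.  When
numba is unavailable the callers fall back to the numpy paths.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally installed
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def lengths_kernel(
    qb,            # (B, 4)
    pts,           # (N, 3) point table: origins, insertions, bl_a, bl_b
    frames,        # (N,) 0 world / 1 upper / 2 fore
    n_m,           # number of muscles
    bl_idx,        # (nb,) muscle indices with bending lines
    normals,       # (nb, 3)
    n_frames,      # (nb,)
    l_arm,
):  # pragma: no cover - exercised via muscle_lengths
    b = qb.shape[0]
    n = pts.shape[0]
    nb = bl_idx.shape[0]
    out = np.empty((b, n_m))
    world = np.empty((n, 3))
    for ib in range(b):
        al, be, ga, de = qb[ib, 0], qb[ib, 1], qb[ib, 2], qb[ib, 3]
        ca, sa = np.cos(al), np.sin(al)
        cb_, sb = np.cos(be), np.sin(be)
        cg, sg = np.cos(ga), np.sin(ga)
        cd, sd = np.cos(de), np.sin(de)
        r00 = ca * cg - sa * cb_ * sg
        r01 = -ca * sg - sa * cb_ * cg
        r02 = sa * sb
        r10 = sa * cg + ca * cb_ * sg
        r11 = -sa * sg + ca * cb_ * cg
        r12 = -ca * sb
        r20 = sb * sg
        r21 = sb * cg
        r22 = cb_
        for i in range(n):
            x, y, z = pts[i, 0], pts[i, 1], pts[i, 2]
            f = frames[i]
            if f == 0:
                world[i, 0] = x
                world[i, 1] = y
                world[i, 2] = z
            else:
                if f == 2:
                    y2 = cd * y - sd * z
                    z2 = sd * y + cd * z - l_arm
                    y, z = y2, z2
                world[i, 0] = r00 * x + r01 * y + r02 * z
                world[i, 1] = r10 * x + r11 * y + r12 * z
                world[i, 2] = r20 * x + r21 * y + r22 * z
        for im in range(n_m):
            dx = world[n_m + im, 0] - world[im, 0]
            dy = world[n_m + im, 1] - world[im, 1]
            dz = world[n_m + im, 2] - world[im, 2]
            out[ib, im] = np.sqrt(dx * dx + dy * dy + dz * dz)
        for kbl in range(nb):
            im = bl_idx[kbl]
            a0 = world[2 * n_m + kbl]
            b0 = world[2 * n_m + nb + kbl]
            p1 = world[im]
            p2 = world[n_m + im]
            # wrap normal in world frame
            nx, ny, nz = normals[kbl, 0], normals[kbl, 1], normals[kbl, 2]
            nf = n_frames[kbl]
            if nf != 0:
                if nf == 2:
                    y2 = cd * ny - sd * nz
                    z2 = sd * ny + cd * nz
                    ny, nz = y2, z2
                nx2 = r00 * nx + r01 * ny + r02 * nz
                ny2 = r10 * nx + r11 * ny + r12 * nz
                nz2 = r20 * nx + r21 * ny + r22 * nz
                nx, ny, nz = nx2, ny2, nz2
            dxl = b0[0] - a0[0]
            dyl = b0[1] - a0[1]
            dzl = b0[2] - a0[2]
            dd = dxl * dxl + dyl * dyl + dzl * dzl
            ux = p2[0] - p1[0]
            uy = p2[1] - p1[1]
            uz = p2[2] - p1[2]
            uu = ux * ux + uy * uy + uz * uz
            ud = ux * dxl + uy * dyl + uz * dzl
            w0x = p1[0] - a0[0]
            w0y = p1[1] - a0[1]
            w0z = p1[2] - a0[2]
            w0d = w0x * dxl + w0y * dyl + w0z * dzl
            w0u = w0x * ux + w0y * uy + w0z * uz
            den = uu * dd - ud * ud
            if den < 1e-14 * uu * dd + 1e-30:
                t_off = w0d / dd
                ox = w0x - t_off * dxl
                oy = w0y - t_off * dyl
                oz = w0z - t_off * dzl
            else:
                s = (ud * w0d - dd * w0u) / den
                if s < 0.0:
                    s = 0.0
                elif s > 1.0:
                    s = 1.0
                pmx = p1[0] + s * ux
                pmy = p1[1] + s * uy
                pmz = p1[2] + s * uz
                t_off = ((pmx - a0[0]) * dxl + (pmy - a0[1]) * dyl + (pmz - a0[2]) * dzl) / dd
                ox = pmx - (a0[0] + t_off * dxl)
                oy = pmy - (a0[1] + t_off * dyl)
                oz = pmz - (a0[2] + t_off * dzl)
            if ox * nx + oy * ny + oz * nz < 0.0:
                t1 = w0d / dd
                t2 = ((p2[0] - a0[0]) * dxl + (p2[1] - a0[1]) * dyl + (p2[2] - a0[2]) * dzl) / dd
                e1x = p1[0] - (a0[0] + t1 * dxl)
                e1y = p1[1] - (a0[1] + t1 * dyl)
                e1z = p1[2] - (a0[2] + t1 * dzl)
                e2x = p2[0] - (a0[0] + t2 * dxl)
                e2y = p2[1] - (a0[1] + t2 * dyl)
                e2z = p2[2] - (a0[2] + t2 * dzl)
                r1 = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
                r2 = np.sqrt(e2x * e2x + e2y * e2y + e2z * e2z)
                if r1 + r2 < 1e-15:
                    tt = 0.5 * (t1 + t2)
                else:
                    tt = (t1 * r2 + t2 * r1) / (r1 + r2)
                if tt < 0.0:
                    tt = 0.0
                elif tt > 1.0:
                    tt = 1.0
                vx = a0[0] + tt * dxl
                vy = a0[1] + tt * dyl
                vz = a0[2] + tt * dzl
                d1 = np.sqrt((p1[0] - vx) ** 2 + (p1[1] - vy) ** 2 + (p1[2] - vz) ** 2)
                d2 = np.sqrt((p2[0] - vx) ** 2 + (p2[1] - vy) ** 2 + (p2[2] - vz) ** 2)
                out[ib, im] = d1 + d2
    return out


@njit(cache=True)
def mass_kernel(q, l_arm, l_farm, m1, m2, r1, r2):  # pragma: no cover
    b = q.shape[0]
    out = np.empty((b, 4, 4))
    i1_perp = m1 * (3.0 * r1 * r1 + l_arm * l_arm) / 12.0
    i1_ax = 0.5 * m1 * r1 * r1
    i2_perp = m2 * (3.0 * r2 * r2 + l_farm * l_farm) / 12.0
    i2_ax = 0.5 * m2 * r2 * r2
    w1 = np.zeros((3, 4))
    w2 = np.zeros((3, 4))
    v1 = np.zeros((3, 4))
    v2 = np.zeros((3, 4))
    for ib in range(b):
        al, be, ga, de = q[ib, 0], q[ib, 1], q[ib, 2], q[ib, 3]
        ca, sa = np.cos(al), np.sin(al)
        cb_, sb = np.cos(be), np.sin(be)
        cg, sg = np.cos(ga), np.sin(ga)
        cd, sd = np.cos(de), np.sin(de)
        rs = np.empty((3, 3))
        rs[0, 0] = ca * cg - sa * cb_ * sg
        rs[0, 1] = -ca * sg - sa * cb_ * cg
        rs[0, 2] = sa * sb
        rs[1, 0] = sa * cg + ca * cb_ * sg
        rs[1, 1] = -sa * sg + ca * cb_ * cg
        rs[1, 2] = -ca * sb
        rs[2, 0] = sb * sg
        rs[2, 1] = sb * cg
        rs[2, 2] = cb_
        # angular velocity maps
        for i in range(3):
            w1[i, 0] = 0.0
            w1[i, 1] = 0.0
            w1[i, 2] = 0.0
            w1[i, 3] = 0.0
        w1[2, 0] = 1.0
        w1[0, 1] = ca
        w1[1, 1] = sa
        w1[0, 2] = sa * sb
        w1[1, 2] = -ca * sb
        w1[2, 2] = cb_
        for i in range(3):
            for j in range(4):
                w2[i, j] = w1[i, j]
        w2[0, 3] = rs[0, 0]
        w2[1, 3] = rs[1, 0]
        w2[2, 3] = rs[2, 0]
        # COM positions
        c1x = -0.5 * l_arm * rs[0, 2]
        c1y = -0.5 * l_arm * rs[1, 2]
        c1z = -0.5 * l_arm * rs[2, 2]
        ex = -l_arm * rs[0, 2]
        ey = -l_arm * rs[1, 2]
        ez = -l_arm * rs[2, 2]
        # forearm COM offset (world): rs @ (0, 0.5*l_farm*sd, -0.5*l_farm*cd)
        ly = 0.5 * l_farm * sd
        lz = -0.5 * l_farm * cd
        r2x = rs[0, 1] * ly + rs[0, 2] * lz
        r2y = rs[1, 1] * ly + rs[1, 2] * lz
        r2z = rs[2, 1] * ly + rs[2, 2] * lz
        for j in range(4):
            # v = -skew(c) @ w = -(c x w), i.e. w x c
            v1[0, j] = -(c1y * w1[2, j] - c1z * w1[1, j])
            v1[1, j] = -(c1z * w1[0, j] - c1x * w1[2, j])
            v1[2, j] = -(c1x * w1[1, j] - c1y * w1[0, j])
            v2[0, j] = -(ey * w1[2, j] - ez * w1[1, j]) - (
                r2y * w2[2, j] - r2z * w2[1, j]
            )
            v2[1, j] = -(ez * w1[0, j] - ex * w1[2, j]) - (
                r2z * w2[0, j] - r2x * w2[2, j]
            )
            v2[2, j] = -(ex * w1[1, j] - ey * w1[0, j]) - (
                r2x * w2[1, j] - r2y * w2[0, j]
            )
        # world inertias: I_w = R diag R^T with body z axis = column 2 (upper)
        # and forearm frame rs @ rx(delta)
        # upper arm world inertia
        i1 = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                i1[i, j] = (
                    i1_perp * (rs[i, 0] * rs[j, 0] + rs[i, 1] * rs[j, 1])
                    + i1_ax * rs[i, 2] * rs[j, 2]
                )
        rf = np.empty((3, 3))
        for i in range(3):
            rf[i, 0] = rs[i, 0]
            rf[i, 1] = rs[i, 1] * cd + rs[i, 2] * sd
            rf[i, 2] = -rs[i, 1] * sd + rs[i, 2] * cd
        i2 = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                i2[i, j] = (
                    i2_perp * (rf[i, 0] * rf[j, 0] + rf[i, 1] * rf[j, 1])
                    + i2_ax * rf[i, 2] * rf[j, 2]
                )
        for i in range(4):
            for j in range(4):
                acc = 0.0
                for k in range(3):
                    acc += m1 * v1[k, i] * v1[k, j] + m2 * v2[k, i] * v2[k, j]
                    for l in range(3):
                        acc += w1[k, i] * i1[k, l] * w1[l, j]
                        acc += w2[k, i] * i2[k, l] * w2[l, j]
                out[ib, i, j] = acc
    return out
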