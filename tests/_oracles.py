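"""Slow, independent reference implementations used as test oracles."""

import numpy as np


def minmod(a, b):
    if a * b <= 0:
        return 0.0
    return np.sign(a) * min(abs(a), abs(b))


def dense_transport_step(op, c, dt, theta=1.0):
    """Scalar-loop reference for one post-deflation transport step.

    Replicates the finite-volume scheme cell by cell: harmonic-mean face
    diffusivity, minmod-limited upwind advection with first-order
    fallback at non-tissue neighbors, adventitial sink faces, and the
    blended lumen-interface flux.  Independent of the vectorised path.
    """
    grid = op.grid
    h = op.h
    ny, nx = grid.shape
    tissue = op.tissue
    D = op.Dcell
    u, v = op.flow.u, op.flow.v
    out = c.copy()

    def tis(j, i):
        return 0 <= j < ny and 0 <= i < nx and tissue[j, i]

    def cval(j, i):
        return c[j, i] if tis(j, i) else 0.0

    def face_value(cm2, cm1, cp1, cp2, vm2, vm1, vp1, vp2, vel):
        s_up = (cm1 - cm2) if (vm1 and vm2) else 0.0
        s_mid = (cp1 - cm1) if (vm1 and vp1) else 0.0
        s_dn = (cp2 - cp1) if (vp1 and vp2) else 0.0
        if vel >= 0:
            return cm1 + 0.5 * minmod(s_up, s_mid)
        return cp1 - 0.5 * minmod(s_dn, s_mid)

    for j in range(ny):
        for i in range(nx):
            if not tissue[j, i]:
                continue
            rate = 0.0
            # x faces
            for face_i, direction in ((i, -1), (i + 1, +1)):
                jn, in_ = j, (i - 1 if direction < 0 else i + 1)
                vel = u[j, face_i]
                if tis(jn, in_):
                    Df = 2 * D[j, i] * D[jn, in_] / (D[j, i] + D[jn, in_])
                    diff = Df * (cval(jn, in_) - c[j, i]) / h
                    if direction < 0:
                        cf = face_value(cval(j, i - 2), cval(j, i - 1),
                                        c[j, i], cval(j, i + 1),
                                        tis(j, i - 2), True, True,
                                        tis(j, i + 1), vel)
                        adv = vel * cf * (1 if op.convection else 0)
                        rate += diff + adv
                    else:
                        cf = face_value(cval(j, i - 1), c[j, i],
                                        cval(j, i + 1), cval(j, i + 2),
                                        tis(j, i - 1), True,
                                        tis(j, i + 1), tis(j, i + 2), vel)
                        adv = vel * cf * (1 if op.convection else 0)
                        rate += diff - adv
            # y faces
            for face_j, direction in ((j, -1), (j + 1, +1)):
                jn = j - 1 if direction < 0 else j + 1
                vel = v[face_j, i]
                if tis(jn, i):
                    Df = 2 * D[j, i] * D[jn, i] / (D[j, i] + D[jn, i])
                    diff = Df * (cval(jn, i) - c[j, i]) / h
                    if direction < 0:
                        cf = face_value(cval(j - 2, i), cval(j - 1, i),
                                        c[j, i], cval(j + 1, i),
                                        tis(j - 2, i), True, True,
                                        tis(j + 1, i), vel)
                        adv = vel * cf * (1 if op.convection else 0)
                        rate += diff + adv
                    else:
                        cf = face_value(cval(j - 1, i), c[j, i],
                                        cval(j + 1, i), cval(j + 2, i),
                                        tis(j - 1, i), True,
                                        tis(j + 1, i), tis(j + 2, i), vel)
                        adv = vel * cf * (1 if op.convection else 0)
                        rate += diff - adv
            out[j, i] = c[j, i] + dt * rate / h

    # boundary faces via the operator's index tables (values recomputed
    # here from first principles)
    cj, ci = op.inner_cells
    for k in range(op.n_inner):
        cc = c[cj[k], ci[k]]
        u_in = op.inner_u_in[k]
        f_nf = max(u_in, 0.0) * cc
        f_sk = min(u_in, 0.0) * cc - op.inner_coef[k] * cc
        out[cj[k], ci[k]] += ((1 - theta) * f_nf + theta * f_sk) * dt / h
    oj, oi = op.outer_cells
    for k in range(len(oj)):
        cc = c[oj[k], oi[k]]
        f = min(op.outer_u_in[k], 0.0) * cc - op.outer_coef[k] * cc
        out[oj[k], oi[k]] += f * dt / h
    return out


def dense_projection(u, v, dom, beta, h):
    """Least-squares pressure projection on a small grid, assembled as a
    dense linear system; the reference for the SOLA correction."""
    tissue = dom.tissue
    cells = np.argwhere(tissue)
    index = {tuple(c): k for k, c in enumerate(cells)}
    n = len(cells)
    A = np.zeros((n, n))
    b = np.zeros(n)
    div = (np.diff(u, axis=1) + np.diff(v, axis=0)) / h
    for (j, i), k in index.items():
        A[k, k] = dom.n_corr[j, i]
        for (dj, di, conn) in ((0, 1, dom.cE), (0, -1, dom.cW),
                               (1, 0, dom.cS), (-1, 0, dom.cN)):
            if conn[j, i]:
                A[k, index[(j + dj, i + di)]] = -1.0
        b[k] = -div[j, i] * h * h / beta
    dP_vec = np.linalg.solve(A, b)
    dP = np.zeros_like(div)
    for (j, i), k in index.items():
        dP[j, i] = dP_vec[k]
    un, vn = u.copy(), v.copy()
    un[:, 1:-1][dom.u_interior[:, 1:-1]] -= (
        beta * (dP[:, 1:] - dP[:, :-1]) / h)[dom.u_interior[:, 1:-1]]
    vn[1:-1, :][dom.v_interior[1:-1, :]] -= (
        beta * (dP[1:, :] - dP[:-1, :]) / h)[dom.v_interior[1:-1, :]]
    un[:, 1:][dom.oE] += beta / h * dP[dom.oE]
    un[:, :-1][dom.oW] -= beta / h * dP[dom.oW]
    vn[1:, :][dom.oS] += beta / h * dP[dom.oS]
    vn[:-1, :][dom.oN] -= beta / h * dP[dom.oN]
    return un, vn
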