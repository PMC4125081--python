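"""Numba kernels: solid angles, writhe/twist sums, and MC sweeps.

All kernels work in internal units (angstroms, radians).  They are thin
numerical cores; argument validation and unit conversion live in the
calling modules.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EZ = np.array([0.0, 0.0, 1.0])


@njit(cache=True, inline="always")
def _cross(a, b):
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


@njit(cache=True, inline="always")
def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


@njit(cache=True, inline="always")
def _norm(a):
    return np.sqrt(a[0] * a[0] + a[1] * a[1] + a[2] * a[2])


@njit(cache=True, inline="always")
def _unit(a):
    n = _norm(a)
    return a / n


@njit(cache=True, inline="always")
def _fold(x):
    """Fold an angle into [-pi, pi)."""
    return x - 2.0 * np.pi * np.floor((x + np.pi) / (2.0 * np.pi))


@njit(cache=True)
def solid_angle_triangle(a, b, c):
    """Signed solid angle of the spherical triangle (a, b, c).

    Van Oosterom-Strackee form; the sign equals sgn((a x b) . c).
    Degenerate (collinear) triples give 0.
    """
    num = _dot(a, _cross(b, c))
    den = 1.0 + _dot(a, b) + _dot(b, c) + _dot(c, a)
    if np.abs(num) < 1e-15 and den <= 0.0:
        return 0.0
    return 2.0 * np.arctan2(num, den)


@njit(cache=True)
def fuller_writhe_sum(t):
    """Fuller (single-sum) writhe in radians for tangent list ``t`` (M, 3).

    The closure segments toward z = -inf/+inf contribute degenerate
    triangles with the pole e_z and are omitted.
    """
    ez = np.array([0.0, 0.0, 1.0])
    w = 0.0
    for i in range(t.shape[0] - 1):
        w += solid_angle_triangle(ez, t[i], t[i + 1])
    return w


@njit(cache=True)
def _asin_clip(x):
    if x > 1.0:
        x = 1.0
    elif x < -1.0:
        x = -1.0
    return np.arcsin(x)


@njit(cache=True)
def segment_pair_solid_angle(p1, p2, p3, p4):
    """Gauss-integral contribution (signed solid angle of the spherical
    quadrangle) of the segment pair (p1->p2, p3->p4)."""
    r13 = p3 - p1
    r14 = p4 - p1
    r23 = p3 - p2
    r24 = p4 - p2
    n1 = _cross(r13, r14)
    n2 = _cross(r14, r24)
    n3 = _cross(r24, r23)
    n4 = _cross(r23, r13)
    m1 = _norm(n1)
    m2 = _norm(n2)
    m3 = _norm(n3)
    m4 = _norm(n4)
    if m1 < 1e-14 or m2 < 1e-14 or m3 < 1e-14 or m4 < 1e-14:
        return 0.0
    n1 = n1 / m1
    n2 = n2 / m2
    n3 = n3 / m3
    n4 = n4 / m4
    om = (
        _asin_clip(_dot(n1, n2))
        + _asin_clip(_dot(n2, n3))
        + _asin_clip(_dot(n3, n4))
        + _asin_clip(_dot(n4, n1))
    )
    s = _dot(_cross(p4 - p3, p2 - p1), r13)
    if s > 0.0:
        return om
    elif s < 0.0:
        return -om
    return 0.0


@njit(cache=True)
def exact_writhe_sum(o):
    """Exact open-curve writhe (radians) of the vertex polyline ``o`` (N, 3).

    Closure: straight rays to z = -inf below the first vertex and to
    z = +inf above the last, plus a coplanar return curve at infinity
    whose contributions vanish.  The ray terms are evaluated analytically
    as Fuller-like sums over the translated curves.
    """
    N = o.shape[0]
    ez = np.array([0.0, 0.0, 1.0])
    wr = 0.0
    # polygon-polygon double sum; adjacent and identical pairs vanish
    for i in range(N - 1):
        for j in range(i + 2, N - 1):
            wr += segment_pair_solid_angle(o[i], o[i + 1], o[j], o[j + 1])
    # lower ray: directions from the first vertex
    prev = _unit(o[1] - o[0])
    for j in range(2, N):
        cur = _unit(o[j] - o[0])
        wr += solid_angle_triangle(ez, prev, cur)
        prev = cur
    # upper ray: directions from the last vertex (pole -e_z, negated)
    mez = np.array([0.0, 0.0, -1.0])
    prev = _unit(o[0] - o[N - 1])
    for j in range(1, N):
        if j < N - 1:
            cur = _unit(o[j] - o[N - 1])
        else:
            cur = -_unit(o[N - 1] - o[N - 2])
        wr -= solid_angle_triangle(mez, prev, cur)
        prev = cur
    return wr


@njit(cache=True, inline="always")
def _perp_of(v):
    """A deterministic unit vector perpendicular to unit vector v."""
    if np.abs(v[0]) < 0.9:
        w = _cross(np.array([1.0, 0.0, 0.0]), v)
    else:
        w = _cross(np.array([0.0, 1.0, 0.0]), v)
    return _unit(w)


@njit(cache=True)
def ribbon_twist_sum(t, l):
    """Ribbon twist (radians) of an open discrete ribbon.

    ``t``: (N-1, 3) unit segment tangents; ``l``: (N, 3) unit ribbon
    vectors (one per vertex).  Virtual straight segments toward -z below
    the first vertex and +z above the last supply the terminal reference
    ribbon vectors.  At each vertex the reference ribbon vector is the
    unit binormal b_i = unit(t_{i-1} x t_i), which is normal to both
    adjacent segments; at straight (collinear) vertices any perpendicular
    is a valid gauge and a deterministic one is used.  The per-step twist
    T_i = fold(beta_i + alpha_{i+1} - alpha_i) into [-pi, pi), where
    beta_i is the dihedral b_i - t_i - b_{i+1} and alpha_i is the signed
    angle between l_i and b_i (direct angle, not a projection, so sharp
    bends stay well defined).
    """
    N = l.shape[0]
    ez = np.array([0.0, 0.0, 1.0])
    b = np.empty((N, 3))
    alpha = np.empty(N)
    for j in range(N):
        tin = ez if j == 0 else t[j - 1]
        tout = ez if j == N - 1 else t[j]
        c = _cross(tin, tout)
        nc = _norm(c)
        if nc > 1e-12:
            b[j] = c / nc
        else:
            b[j] = _perp_of(tout)
        # signed angle between l_j and b_j about the vertex bisector
        u = tin + tout
        nu = _norm(u)
        if nu > 1e-8:
            u = u / nu
        else:
            u = tout
        ca = _dot(b[j], l[j])
        if ca > 1.0:
            ca = 1.0
        elif ca < -1.0:
            ca = -1.0
        ang = np.arccos(ca)
        if _dot(_cross(b[j], l[j]), u) < 0.0:
            ang = -ang
        alpha[j] = ang
    tw = 0.0
    for i in range(N - 1):
        beta = np.arctan2(_dot(_cross(b[i], b[i + 1]), t[i]), _dot(b[i], b[i + 1]))
        tw += _fold(beta + alpha[i + 1] - alpha[i])
    return tw


# ---------------------------------------------------------------------------
# Monte Carlo sweeps
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _matvec(M, v):
    return np.array(
        [
            M[0, 0] * v[0] + M[0, 1] * v[1] + M[0, 2] * v[2],
            M[1, 0] * v[0] + M[1, 1] * v[1] + M[1, 2] * v[2],
            M[2, 0] * v[0] + M[2, 1] * v[1] + M[2, 2] * v[2],
        ]
    )


@njit(cache=True, inline="always")
def _matmul33(A, B):
    C = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            C[i, j] = A[i, 0] * B[0, j] + A[i, 1] * B[1, j] + A[i, 2] * B[2, j]
    return C


@njit(cache=True, inline="always")
def _matmul33_t2(A, B):
    """A @ B.T for 3x3 matrices."""
    C = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            C[i, j] = A[i, 0] * B[j, 0] + A[i, 1] * B[j, 1] + A[i, 2] * B[j, 2]
    return C


@njit(cache=True, inline="always")
def _orthonormalize(M):
    """Gram-Schmidt re-orthonormalization of a near-rotation matrix.

    Applied to every block rotation in the constrained sweep: without
    it, frame non-orthonormality compounds double-exponentially along
    the chain (each accepted move squares the error of the frames it is
    built from).
    """
    a = M[:, 0]
    a = a / _norm(a)
    b = M[:, 1]
    b = b - _dot(a, b) * a
    b = b / _norm(b)
    c = _cross(a, b)
    out = np.empty((3, 3))
    out[:, 0] = a
    out[:, 1] = b
    out[:, 2] = c
    return out


@njit(cache=True)
def rebuild_frames(R, d, origins, frames):
    """Recompute global origins/frames from local step transforms, in place."""
    n = R.shape[0] + 1
    origins[0, 0] = 0.0
    origins[0, 1] = 0.0
    origins[0, 2] = 0.0
    frames[0] = np.eye(3)
    for i in range(n - 1):
        origins[i + 1] = origins[i] + _matvec(frames[i], d[i])
        frames[i + 1] = _matmul33(frames[i], R[i])


@njit(cache=True)
def sweep_force(
    params, Rs, ds, prop_params, Rp, dp, unif, force_pn, xy_k, kbt_pnnm
):
    """One sequential Metropolis sweep with a stretching-force energy.

    ``params``/``Rs``/``ds`` are the current step parameters (internal
    units) and their local transforms; ``prop_*`` the proposed ones.
    Energy: E = -F*z (+ optional harmonic xy restraint on the terminal
    base pair), z in angstroms converted to pN*nm internally.
    Returns the number of accepted proposals.
    """
    m = Rs.shape[0]
    # suffix vectors: terminal origin relative to frame j origin, frame j coords
    S = np.zeros((m + 1, 3))
    for j in range(m - 1, -1, -1):
        S[j] = ds[j] + _matvec(Rs[j], S[j + 1])
    G = np.eye(3)
    o = np.zeros(3)
    naccept = 0
    for i in range(m):
        term_old = o + _matvec(G, ds[i] + _matvec(Rs[i], S[i + 1]))
        term_new = o + _matvec(G, dp[i] + _matvec(Rp[i], S[i + 1]))
        dE = -force_pn * (term_new[2] - term_old[2]) * 0.1
        if xy_k > 0.0:
            dE += (
                0.5
                * xy_k
                * (
                    term_new[0] ** 2
                    + term_new[1] ** 2
                    - term_old[0] ** 2
                    - term_old[1] ** 2
                )
                * 0.1
            )
        if dE <= 0.0 or unif[i] < np.exp(-dE / kbt_pnnm):
            Rs[i] = Rp[i]
            ds[i] = dp[i]
            params[i] = prop_params[i]
            naccept += 1
        o = o + _matvec(G, ds[i])
        G = _matmul33(G, Rs[i])
    return naccept


@njit(cache=True)
def _topology_candidate(t, l, i, A, ti_new):
    """Twist + Fuller writhe of the state with step ``i`` replaced.

    Candidate tangents: t[j] for j < i, ``ti_new`` at j == i, A @ t[j]
    for j > i; candidate ribbon vectors rotate by A for vertices > i.
    Pass i < 0 (with any A/ti_new) to evaluate the current state.
    Fully scalarized streaming evaluation (no temporaries): this runs
    once per single-step proposal in constrained simulations.
    """
    n = l.shape[0]
    m = n - 1
    tw = 0.0
    wr = 0.0
    # previous tangent (virtual lower segment points +z)
    ptx = 0.0
    pty = 0.0
    ptz = 1.0
    pbx = 0.0
    pby = 0.0
    pbz = 0.0
    palpha = 0.0
    a00 = A[0, 0]
    a01 = A[0, 1]
    a02 = A[0, 2]
    a10 = A[1, 0]
    a11 = A[1, 1]
    a12 = A[1, 2]
    a20 = A[2, 0]
    a21 = A[2, 1]
    a22 = A[2, 2]
    for j in range(n):
        # candidate tangent out of vertex j
        if j < m:
            if i < 0 or j < i:
                tox = t[j, 0]
                toy = t[j, 1]
                toz = t[j, 2]
            elif j == i:
                tox = ti_new[0]
                toy = ti_new[1]
                toz = ti_new[2]
            else:
                x = t[j, 0]
                y = t[j, 1]
                z = t[j, 2]
                tox = a00 * x + a01 * y + a02 * z
                toy = a10 * x + a11 * y + a12 * z
                toz = a20 * x + a21 * y + a22 * z
        else:
            tox = 0.0
            toy = 0.0
            toz = 1.0
        # candidate ribbon vector at vertex j
        if i < 0 or j <= i:
            lx = l[j, 0]
            ly = l[j, 1]
            lz = l[j, 2]
        else:
            x = l[j, 0]
            y = l[j, 1]
            z = l[j, 2]
            lx = a00 * x + a01 * y + a02 * z
            ly = a10 * x + a11 * y + a12 * z
            lz = a20 * x + a21 * y + a22 * z
        # reference binormal b_j = unit(t_in x t_out), gauge at straight vertices
        cx = pty * toz - ptz * toy
        cy = ptz * tox - ptx * toz
        cz = ptx * toy - pty * tox
        nc = np.sqrt(cx * cx + cy * cy + cz * cz)
        if nc > 1e-12:
            bx = cx / nc
            by = cy / nc
            bz = cz / nc
        else:
            if np.abs(tox) < 0.9:  # perp of tout seeded from x (or y) axis
                qx = 0.0
                qy = -toz
                qz = toy
            else:
                qx = toz
                qy = 0.0
                qz = -tox
            nq = np.sqrt(qx * qx + qy * qy + qz * qz)
            bx = qx / nq
            by = qy / nq
            bz = qz / nq
        # alpha_j: signed angle from b_j to l_j about the vertex bisector
        ux = ptx + tox
        uy = pty + toy
        uz = ptz + toz
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        if nu > 1e-8:
            ux /= nu
            uy /= nu
            uz /= nu
        else:
            ux = tox
            uy = toy
            uz = toz
        ca = bx * lx + by * ly + bz * lz
        if ca > 1.0:
            ca = 1.0
        elif ca < -1.0:
            ca = -1.0
        alpha = np.arccos(ca)
        sx = by * lz - bz * ly
        sy = bz * lx - bx * lz
        sz = bx * ly - by * lx
        if sx * ux + sy * uy + sz * uz < 0.0:
            alpha = -alpha
        if j > 0:
            # beta_{j-1}: dihedral from b_{j-1} to b_j about t_{j-1}
            wx = pby * bz - pbz * by
            wy = pbz * bx - pbx * bz
            wz = pbx * by - pby * bx
            beta = np.arctan2(
                wx * ptx + wy * pty + wz * ptz, pbx * bx + pby * by + pbz * bz
            )
            tw += _fold(beta + alpha - palpha)
            if j <= m - 1:
                # Fuller triangle (e_z, t_{j-1}, t_j)
                num = ptx * toy - pty * tox
                den = 1.0 + ptz + toz + ptx * tox + pty * toy + ptz * toz
                if np.abs(num) >= 1e-15 or den > 0.0:
                    wr += 2.0 * np.arctan2(num, den)
        ptx = tox
        pty = toy
        ptz = toz
        pbx = bx
        pby = by
        pbz = bz
        palpha = alpha
    return tw, wr


@njit(cache=True)
def sweep_link_constrained(
    params,
    Rs,
    ds,
    prop_params,
    Rp,
    dp,
    unif,
    origins,
    frames,
    force_pn,
    k_rot,
    link_target,
    xy_k,
    kbt_pnnm,
):
    """One sequential sweep with force + torsional-trap energy.

    The link is re-evaluated after every single-step proposal using the
    Fuller writhe (O(N) per proposal) plus the discrete ribbon twist.
    ``origins``/``frames`` are kept consistent in place (the state is
    rebuilt from the local transforms at sweep start, so frame drift
    does not accumulate across sweeps).  Returns (n_accepted, link,
    twist, writhe) for the final state.
    """
    m = Rs.shape[0]
    n = m + 1
    rebuild_frames(Rs, ds, origins, frames)
    t = np.empty((m, 3))
    l = np.empty((n, 3))
    for j in range(m):
        t[j] = _unit(origins[j + 1] - origins[j])
    for j in range(n):
        l[j, 0] = frames[j, 0, 1]
        l[j, 1] = frames[j, 1, 1]
        l[j, 2] = frames[j, 2, 1]
    eye = np.eye(3)
    zero3 = np.zeros(3)
    tw, wr = _topology_candidate(t, l, -1, eye, zero3)
    lk = tw + wr
    naccept = 0
    for i in range(m):
        Gi = frames[i]
        A = _orthonormalize(
            _matmul33_t2(_matmul33_t2(_matmul33(Gi, Rp[i]), Rs[i]), Gi)
        )
        p_new = origins[i] + _matvec(Gi, dp[i])
        q_old = origins[i + 1].copy()  # origins[i+1] is overwritten on accept
        ti_new = _unit(p_new - origins[i])
        term = p_new + _matvec(A, origins[n - 1] - q_old)
        tw2, wr2 = _topology_candidate(t, l, i, A, ti_new)
        lk2 = tw2 + wr2
        dE = -force_pn * (term[2] - origins[n - 1, 2]) * 0.1
        dE += 0.5 * k_rot * ((lk2 - link_target) ** 2 - (lk - link_target) ** 2)
        if xy_k > 0.0:
            dE += (
                0.5
                * xy_k
                * (
                    term[0] ** 2
                    + term[1] ** 2
                    - origins[n - 1, 0] ** 2
                    - origins[n - 1, 1] ** 2
                )
                * 0.1
            )
        if dE <= 0.0 or unif[i] < np.exp(-dE / kbt_pnnm):
            naccept += 1
            Rs[i] = Rp[i]
            ds[i] = dp[i]
            params[i] = prop_params[i]
            origins[i + 1] = p_new
            frames[i + 1] = _matmul33(A, frames[i + 1])
            for j in range(i + 2, n):
                x = origins[j, 0] - q_old[0]
                y = origins[j, 1] - q_old[1]
                z = origins[j, 2] - q_old[2]
                origins[j, 0] = p_new[0] + A[0, 0] * x + A[0, 1] * y + A[0, 2] * z
                origins[j, 1] = p_new[1] + A[1, 0] * x + A[1, 1] * y + A[1, 2] * z
                origins[j, 2] = p_new[2] + A[2, 0] * x + A[2, 1] * y + A[2, 2] * z
                frames[j] = _matmul33(A, frames[j])
            t[i] = ti_new
            for j in range(i + 1, m):
                x = t[j, 0]
                y = t[j, 1]
                z = t[j, 2]
                t[j, 0] = A[0, 0] * x + A[0, 1] * y + A[0, 2] * z
                t[j, 1] = A[1, 0] * x + A[1, 1] * y + A[1, 2] * z
                t[j, 2] = A[2, 0] * x + A[2, 1] * y + A[2, 2] * z
            for j in range(i + 1, n):
                x = l[j, 0]
                y = l[j, 1]
                z = l[j, 2]
                l[j, 0] = A[0, 0] * x + A[0, 1] * y + A[0, 2] * z
                l[j, 1] = A[1, 0] * x + A[1, 1] * y + A[1, 2] * z
                l[j, 2] = A[2, 0] * x + A[2, 1] * y + A[2, 2] * z
            tw = tw2
            wr = wr2
            lk = lk2
    return naccept, lk, tw, wr
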