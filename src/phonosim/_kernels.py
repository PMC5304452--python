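"""Jitted inner loop of the acoustic subcycling.

The LPCE solver runs 20 Runge-Kutta substeps inside every flow step; at
desk-scale grid sizes that loop is the whole simulation budget, so it is
fused into a single numba kernel: banded compact-derivative solves
(Thomas algorithm per grid line), sparse B/filter matvecs, the LPCE
right-hand side, and the boundary conditions.  The pure
numpy/scipy path in :mod:`phonosim.acoustics` remains as the reference
implementation and fallback; a unit test asserts both paths agree.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dep of the fast path
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


# edge condition codes
EDGE_NONE, EDGE_WALL, EDGE_INLET, EDGE_OPEN = 0, 1, 2, 3


@njit(cache=True, fastmath=True)
def _csr_mm(indptr, indices, data, X, out):
    N, m = out.shape
    for i in range(N):
        for c in range(m):
            out[i, c] = 0.0
        for jj in range(indptr[i], indptr[i + 1]):
            j = indices[jj]
            v = data[jj]
            for c in range(m):
                out[i, c] += v * X[j, c]


@njit(cache=True, fastmath=True)
def _thomas(g, sub, dia, sup, n_lines, line_len, base_step, stride):
    """Solve the (per-line) tridiagonal systems A x = g in place.

    Coefficients are per-node arrays in the same flat ordering as g; runs
    never cross line boundaries so sub/sup vanish there.
    """
    m = g.shape[1]
    cp = np.empty(line_len)
    for line in range(n_lines):
        base = line * base_step
        fi = base
        w = dia[fi]
        cp[0] = sup[fi] / w
        for c in range(m):
            g[fi, c] = g[fi, c] / w
        prev = fi
        for k in range(1, line_len):
            fi = base + k * stride
            w = dia[fi] - sub[fi] * cp[k - 1]
            cp[k] = sup[fi] / w
            for c in range(m):
                g[fi, c] = (g[fi, c] - sub[fi] * g[prev, c]) / w
            prev = fi
        for k in range(line_len - 2, -1, -1):
            fi = base + k * stride
            nxt = base + (k + 1) * stride
            for c in range(m):
                g[fi, c] -= cp[k] * g[nxt, c]


@njit(cache=True, fastmath=True)
def _apply_bc(
    X,
    edge_kind,
    edge_axis,
    edge_off,
    edge_idx,
    edge_inner,
    ghost_flat,
    stencil,
    weights,
    normals,
    solid_flat,
):
    dim = 2
    ip = dim + 1
    for e in range(edge_kind.size):
        kind = edge_kind[e]
        if kind == EDGE_NONE:
            continue
        ax = edge_axis[e]
        for q in range(edge_off[e], edge_off[e + 1]):
            i = edge_idx[q]
            if kind == EDGE_WALL:
                X[i, 1 + ax] = 0.0
            elif kind == EDGE_INLET:
                for c in range(ip + 1):
                    X[i, c] = 0.0
            else:  # open: p' = 0, zero-gradient velocity
                X[i, ip] = 0.0
                j = edge_inner[q]
                for c in range(1, 1 + dim):
                    X[i, c] = X[j, c]
    ng = ghost_flat.size
    ns = stencil.shape[1]
    for k in range(ng):
        g = ghost_flat[k]
        r = 0.0
        pz = 0.0
        v0 = 0.0
        v1 = 0.0
        for s in range(ns):
            j = stencil[k, s]
            w = weights[k, s]
            r += w * X[j, 0]
            pz += w * X[j, ip]
            v0 += w * X[j, 1]
            v1 += w * X[j, 2]
        X[g, 0] = r
        X[g, ip] = pz
        vn = v0 * normals[k, 0] + v1 * normals[k, 1]
        X[g, 1] = v0 - 2.0 * vn * normals[k, 0]
        X[g, 2] = v1 - 2.0 * vn * normals[k, 1]
    for k in range(solid_flat.size):
        i = solid_flat[k]
        for c in range(ip + 1):
            X[i, c] = 0.0


@njit(cache=True, fastmath=True)
def _rhs(d0, d1, X, Uf, gPf, negGPabs, srcf, rho0, has_U, has_gP, has_src, out, solid_flat):
    N = X.shape[0]
    inv_rho0 = 1.0 / rho0
    for i in range(N):
        divu = d0[i, 1] + d1[i, 2]
        o0 = -rho0 * divu
        op = negGPabs[i] * divu
        if has_src:
            op -= srcf[i]
        o1 = -inv_rho0 * d0[i, 3]
        o2 = -inv_rho0 * d1[i, 3]
        if has_U:
            o1 -= d0[i, 4]
            o2 -= d1[i, 4]
            o0 -= Uf[0, i] * d0[i, 0] + Uf[1, i] * d1[i, 0]
            op -= Uf[0, i] * d0[i, 3] + Uf[1, i] * d1[i, 3]
        if has_gP:
            op -= X[i, 1] * gPf[0, i] + X[i, 2] * gPf[1, i]
        out[i, 0] = o0
        out[i, 1] = o1
        out[i, 2] = o2
        out[i, 3] = op
    for k in range(solid_flat.size):
        i = solid_flat[k]
        for c in range(4):
            out[i, c] = 0.0


@njit(cache=True, fastmath=True)
def lpce_subcycles(
    X,
    n_sub,
    dt,
    nx,
    ny,
    rho0,
    # axis operators: B (csr), tridiag A, inverse metric
    b0_indptr, b0_indices, b0_data, sub0, dia0, sup0, invm0,
    b1_indptr, b1_indices, b1_data, sub1, dia1, sup1, invm1,
    # filters (csr), applied when sigma_on
    f0_indptr, f0_indices, f0_data, f1_indptr, f1_indices, f1_data, sigma_on,
    # frozen mean flow
    Uf, gPf, negGPabs, srcf, has_U, has_gP, has_src,
    # boundary data
    edge_kind, edge_axis, edge_off, edge_idx, edge_inner,
    ghost_flat, stencil, weights, normals, solid_flat,
):
    """Advance n_sub RK4 substeps; X is (N, 5): rho', u', v', p', work."""
    N = X.shape[0]
    nf = 4
    W = np.empty((N, 5))
    d0 = np.empty((N, 5))
    d1 = np.empty((N, 5))
    K1 = np.empty((N, nf))
    K2 = np.empty((N, nf))
    K3 = np.empty((N, nf))
    K4 = np.empty((N, nf))
    Xt = np.empty((N, nf))
    Xs = X[:, :nf]

    for _ in range(n_sub):
        _apply_bc(Xs, edge_kind, edge_axis, edge_off, edge_idx, edge_inner,
                  ghost_flat, stencil, weights, normals, solid_flat)
        _stage(Xs, W, d0, d1, K1,
               b0_indptr, b0_indices, b0_data, sub0, dia0, sup0, invm0,
               b1_indptr, b1_indices, b1_data, sub1, dia1, sup1, invm1,
               nx, ny, rho0, Uf, gPf, negGPabs, srcf, has_U, has_gP, has_src,
               solid_flat)
        for i in range(N):
            for c in range(nf):
                Xt[i, c] = Xs[i, c] + 0.5 * dt * K1[i, c]
        _apply_bc(Xt, edge_kind, edge_axis, edge_off, edge_idx, edge_inner,
                  ghost_flat, stencil, weights, normals, solid_flat)
        _stage(Xt, W, d0, d1, K2,
               b0_indptr, b0_indices, b0_data, sub0, dia0, sup0, invm0,
               b1_indptr, b1_indices, b1_data, sub1, dia1, sup1, invm1,
               nx, ny, rho0, Uf, gPf, negGPabs, srcf, has_U, has_gP, has_src,
               solid_flat)
        for i in range(N):
            for c in range(nf):
                Xt[i, c] = Xs[i, c] + 0.5 * dt * K2[i, c]
        _apply_bc(Xt, edge_kind, edge_axis, edge_off, edge_idx, edge_inner,
                  ghost_flat, stencil, weights, normals, solid_flat)
        _stage(Xt, W, d0, d1, K3,
               b0_indptr, b0_indices, b0_data, sub0, dia0, sup0, invm0,
               b1_indptr, b1_indices, b1_data, sub1, dia1, sup1, invm1,
               nx, ny, rho0, Uf, gPf, negGPabs, srcf, has_U, has_gP, has_src,
               solid_flat)
        for i in range(N):
            for c in range(nf):
                Xt[i, c] = Xs[i, c] + dt * K3[i, c]
        _apply_bc(Xt, edge_kind, edge_axis, edge_off, edge_idx, edge_inner,
                  ghost_flat, stencil, weights, normals, solid_flat)
        _stage(Xt, W, d0, d1, K4,
               b0_indptr, b0_indices, b0_data, sub0, dia0, sup0, invm0,
               b1_indptr, b1_indices, b1_data, sub1, dia1, sup1, invm1,
               nx, ny, rho0, Uf, gPf, negGPabs, srcf, has_U, has_gP, has_src,
               solid_flat)
        for i in range(N):
            for c in range(nf):
                Xs[i, c] += dt / 6.0 * (
                    K1[i, c] + 2.0 * K2[i, c] + 2.0 * K3[i, c] + K4[i, c]
                )
        _apply_bc(Xs, edge_kind, edge_axis, edge_off, edge_idx, edge_inner,
                  ghost_flat, stencil, weights, normals, solid_flat)
        if sigma_on:
            _csr_mm(f0_indptr, f0_indices, f0_data, Xs, Xt)
            _csr_mm(f1_indptr, f1_indices, f1_data, Xt, Xs)
            _apply_bc(Xs, edge_kind, edge_axis, edge_off, edge_idx, edge_inner,
                      ghost_flat, stencil, weights, normals, solid_flat)
    return X


@njit(cache=True, fastmath=True)
def _stage(
    Xin, W, d0, d1, K,
    b0_indptr, b0_indices, b0_data, sub0, dia0, sup0, invm0,
    b1_indptr, b1_indices, b1_data, sub1, dia1, sup1, invm1,
    nx, ny, rho0, Uf, gPf, negGPabs, srcf, has_U, has_gP, has_src,
    solid_flat,
):
    N = Xin.shape[0]
    for i in range(N):
        for c in range(4):
            W[i, c] = Xin[i, c]
        if has_U:
            W[i, 4] = Xin[i, 1] * Uf[0, i] + Xin[i, 2] * Uf[1, i]
        else:
            W[i, 4] = 0.0
    _csr_mm(b0_indptr, b0_indices, b0_data, W, d0)
    _thomas(d0, sub0, dia0, sup0, ny, nx, 1, ny)
    _csr_mm(b1_indptr, b1_indices, b1_data, W, d1)
    _thomas(d1, sub1, dia1, sup1, nx, ny, ny, 1)
    for i in range(N):
        m0 = invm0[i]
        m1 = invm1[i]
        for c in range(5):
            d0[i, c] *= m0
            d1[i, c] *= m1
    _rhs(d0, d1, Xin, Uf, gPf, negGPabs, srcf, rho0, has_U, has_gP, has_src, K, solid_flat)


@njit(cache=True)
def polygon_sdf(points, poly):
    """Signed distance from 2D points to a closed polygon (negative inside)."""
    n = points.shape[0]
    m = poly.shape[0]
    out = np.empty(n)
    for i in range(n):
        px = points[i, 0]
        py = points[i, 1]
        best = 1.0e300
        inside = False
        for k in range(m):
            ax = poly[k, 0]
            ay = poly[k, 1]
            k2 = k + 1 if k + 1 < m else 0
            bx = poly[k2, 0]
            by = poly[k2, 1]
            dx = bx - ax
            dy = by - ay
            dd = dx * dx + dy * dy
            if dd > 0.0:
                t = ((px - ax) * dx + (py - ay) * dy) / dd
                if t < 0.0:
                    t = 0.0
                elif t > 1.0:
                    t = 1.0
            else:
                t = 0.0
            ex = px - (ax + t * dx)
            ey = py - (ay + t * dy)
            d2 = ex * ex + ey * ey
            if d2 < best:
                best = d2
            if (ay > py) != (by > py):
                xin = ax + (py - ay) / (by - ay) * dx
                if px < xin:
                    inside = not inside
        out[i] = -np.sqrt(best) if inside else np.sqrt(best)
    return out
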