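"""Jitted inner loops for the penalised solvers.

Coordinate-descent sweeps and the weight-block 1-D searches dominate
runtime; they are compiled with numba when available and fall back to
the same pure-Python code otherwise. The scalar proximal operator here
mirrors :mod:`robustcox.penalties` exactly (piecewise-quadratic
candidate enumeration); the test suite asserts their agreement.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


# family codes shared with pencox
F_LASSO, F_RIDGE, F_EN, F_MCP, F_SCAD, F_SNET, F_MNET = 0, 1, 2, 3, 4, 5, 6

FAMILY_CODES = {
    "lasso": F_LASSO,
    "ridge": F_RIDGE,
    "elasticnet": F_EN,
    "mcp": F_MCP,
    "scad": F_SCAD,
    "snet": F_SNET,
    "mnet": F_MNET,
}


@njit(cache=False)
def _pen_scalar(u, fam, lam, gamma, alpha):
    if fam == F_LASSO:
        return lam * u
    if fam == F_RIDGE:
        return 0.5 * lam * u * u
    if fam == F_EN:
        return lam * (alpha * u + 0.5 * (1.0 - alpha) * u * u)
    ridge = 0.0
    lam_nc = lam
    if fam == F_SNET or fam == F_MNET:
        ridge = 0.5 * lam * (1.0 - alpha) * u * u
        lam_nc = alpha * lam
    if fam == F_MCP or fam == F_MNET:
        if u <= gamma * lam_nc:
            return ridge + lam_nc * u - u * u / (2.0 * gamma)
        return ridge + 0.5 * gamma * lam_nc * lam_nc
    # scad / snet
    if u <= lam_nc:
        return ridge + lam_nc * u
    if u <= gamma * lam_nc:
        return ridge - (u * u - 2.0 * gamma * lam_nc * u + lam_nc * lam_nc) / (
            2.0 * (gamma - 1.0)
        )
    return ridge + lam_nc * lam_nc * (gamma * gamma - 1.0) / (2.0 * (gamma - 1.0))


@njit(cache=False)
def _prox_unscaled(z, step, fam, lam, gamma, alpha):
    az = abs(z)
    sign = 1.0 if z >= 0.0 else -1.0
    # quadratic pieces (lo, hi, a, b) of the penalty in u = |beta|
    lo = np.zeros(3)
    hi = np.zeros(3)
    aa = np.zeros(3)
    bb = np.zeros(3)
    if fam == F_LASSO:
        npieces = 1
        hi[0] = math.inf
        bb[0] = lam
    elif fam == F_RIDGE:
        npieces = 1
        hi[0] = math.inf
        aa[0] = 0.5 * lam
    elif fam == F_EN:
        npieces = 1
        hi[0] = math.inf
        aa[0] = 0.5 * lam * (1.0 - alpha)
        bb[0] = lam * alpha
    else:
        ridge_a = 0.0
        lam_nc = lam
        if fam == F_SNET or fam == F_MNET:
            ridge_a = 0.5 * lam * (1.0 - alpha)
            lam_nc = alpha * lam
        if fam == F_MCP or fam == F_MNET:
            npieces = 2
            hi[0] = gamma * lam_nc
            aa[0] = ridge_a - 1.0 / (2.0 * gamma)
            bb[0] = lam_nc
            lo[1] = gamma * lam_nc
            hi[1] = math.inf
            aa[1] = ridge_a
        else:  # scad / snet
            npieces = 3
            hi[0] = lam_nc
            aa[0] = ridge_a
            bb[0] = lam_nc
            lo[1] = lam_nc
            hi[1] = gamma * lam_nc
            aa[1] = ridge_a - 1.0 / (2.0 * (gamma - 1.0))
            bb[1] = gamma * lam_nc / (gamma - 1.0)
            lo[2] = gamma * lam_nc
            hi[2] = math.inf
            aa[2] = ridge_a
    best_b = 0.0
    best_h = 0.5 * az * az / step
    for k in range(npieces):
        curv = 1.0 / step + 2.0 * aa[k]
        top = hi[k] if hi[k] != math.inf else (az if az > lo[k] else lo[k])
        for c in range(3):
            if c == 0:
                if curv <= 0.0:
                    continue
                u = (az / step - bb[k]) / curv
                if u < lo[k]:
                    u = lo[k]
                elif u > top:
                    u = top
            elif c == 1:
                u = lo[k]
            else:
                u = top
            if u < lo[k] - 1e-15 or (hi[k] != math.inf and u > hi[k] + 1e-15):
                continue
            h = 0.5 * (u - az) * (u - az) / step + _pen_scalar(u, fam, lam, gamma, alpha)
            if h < best_h - 1e-15 or (abs(h - best_h) <= 1e-15 and u < best_b):
                best_b = u
                best_h = h
    return sign * best_b


@njit(cache=False)
def prox_kernel(z, step, fam, lam, gamma, alpha, scale):
    if scale == 1.0:
        return _prox_unscaled(z, step, fam, lam, gamma, alpha)
    return scale * _prox_unscaled(z / scale, step / (scale * scale), fam, lam, gamma, alpha)


@njit(cache=False)
def cd_solve(X, dX, res, beta, v, fam, lam, gamma, alpha, scales, tol, max_sweeps):
    """Cyclic coordinate descent on the weighted-least-squares surrogate.

    Mutates beta and res in place; full sweeps alternate with
    active-set sweeps over the current support. Returns max |delta| of
    the final full sweep.
    """
    n, p = X.shape
    maxdel = 0.0
    for _ in range(max_sweeps):
        maxdel = 0.0
        for j in range(p):
            vj = v[j]
            if vj <= 1e-12:
                continue
            s = 0.0
            for i in range(n):
                s += dX[i, j] * res[i]
            zj = s / vj + beta[j]
            bj = prox_kernel(zj, 1.0 / vj, fam, lam, gamma, alpha, scales[j])
            delta = bj - beta[j]
            if delta != 0.0:
                for i in range(n):
                    res[i] -= X[i, j] * delta
                beta[j] = bj
                if abs(delta) > maxdel:
                    maxdel = abs(delta)
        if maxdel < tol:
            break
        for _ in range(max_sweeps):
            maxdel_a = 0.0
            for j in range(p):
                if beta[j] == 0.0:
                    continue
                vj = v[j]
                if vj <= 1e-12:
                    continue
                s = 0.0
                for i in range(n):
                    s += dX[i, j] * res[i]
                zj = s / vj + beta[j]
                bj = prox_kernel(zj, 1.0 / vj, fam, lam, gamma, alpha, scales[j])
                delta = bj - beta[j]
                if delta != 0.0:
                    for i in range(n):
                        res[i] -= X[i, j] * delta
                    beta[j] = bj
                    if abs(delta) > maxdel_a:
                        maxdel_a = abs(delta)
            if maxdel_a < tol:
                break
    return maxdel


@njit(cache=False)
def _weight_slice(vv, k, s_ev, ev_d, r_old, e_i, di, lam1_over_c, n):
    """Objective slice in v = log w_i on [log w_min, 0] (constants in i
    dropped); |v| = -v there."""
    val = -(di / n) * vv - lam1_over_c * vv
    for t in range(k):
        base = s_ev[t] - r_old
        if base < 0.0:
            base = 0.0
        val += ev_d[t] * math.log(base + e_i * math.exp(vv)) / n
    return val


@njit(cache=False)
def weight_sweep(vlog, r, phi_m, status, c, s_ev, ev_d, kcount, lam1, v_lo, n):
    """One cyclic pass of exact 1-D weight updates (golden section on the
    convex slice, compared against both endpoints; descent-only).
    Mutates vlog, r and s_ev in place."""
    invphi = 0.6180339887498949
    for i in range(n):
        k = kcount[i]
        di = status[i]
        if k == 0 and di == 0.0:
            continue
        e_i = math.exp(phi_m[i])
        r_old = r[i]
        lc = lam1 / c[i]
        cur = _weight_slice(vlog[i], k, s_ev, ev_d, r_old, e_i, di, lc, n)
        best_v = vlog[i]
        # golden section on [v_lo, 0]
        a = v_lo
        b = 0.0
        cc = b - invphi * (b - a)
        dd = a + invphi * (b - a)
        fc = _weight_slice(cc, k, s_ev, ev_d, r_old, e_i, di, lc, n)
        fd = _weight_slice(dd, k, s_ev, ev_d, r_old, e_i, di, lc, n)
        for _ in range(40):
            if b - a <= 1e-6:
                break
            if fc < fd:
                b = dd
                dd = cc
                fd = fc
                cc = b - invphi * (b - a)
                fc = _weight_slice(cc, k, s_ev, ev_d, r_old, e_i, di, lc, n)
            else:
                a = cc
                cc = dd
                fc = fd
                dd = a + invphi * (b - a)
                fd = _weight_slice(dd, k, s_ev, ev_d, r_old, e_i, di, lc, n)
        mid = 0.5 * (a + b)
        fmid = _weight_slice(mid, k, s_ev, ev_d, r_old, e_i, di, lc, n)
        f0 = _weight_slice(0.0, k, s_ev, ev_d, r_old, e_i, di, lc, n)
        flo = _weight_slice(v_lo, k, s_ev, ev_d, r_old, e_i, di, lc, n)
        if fmid < cur - 1e-15:
            cur = fmid
            best_v = mid
        if f0 < cur - 1e-15:
            cur = f0
            best_v = 0.0
        if flo < cur - 1e-15:
            cur = flo
            best_v = v_lo
        if best_v != vlog[i]:
            r_new = e_i * math.exp(best_v)
            for t in range(k):
                base = s_ev[t] - r_old
                if base < 0.0:
                    base = 0.0
                s_ev[t] = base + r_new
            r[i] = r_new
            vlog[i] = best_v
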