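"""Independent reference solvers for validating the EBM implementation.

Each function here reaches the same mathematical object as a limiting case
of the EBM program through a *different* derivation, so agreement between
the two routes is a genuine cross-check rather than a tautology:

- :func:`radial_super_score` normalises the radial ratio by pinning phi = 1
  (no Charnes-Cooper transform, inequality constraints);
- :func:`sbm_score` solves the slacks-based measure by Dinkelbach's
  parametric iteration on the fractional objective;
- :func:`brute_force_ebm` minimises the EBM ratio on a refined (theta, phi)
  grid with an inner slack-maximising LP, for tiny instances only.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

__all__ = ["radial_super_score", "sbm_score", "brute_force_ebm"]


def _prep(x, y, u, k, exclude_self):
    x, y, u = (np.atleast_2d(np.asarray(a, float)) for a in (x, y, u))
    n = x.shape[1]
    ref = [j for j in range(n) if j != k] if exclude_self else list(range(n))
    return x, y, u, ref


def radial_super_score(x, y, u, k, exclude_self=True, returns_to_scale="CRS"):
    """Non-oriented radial (super-)efficiency score min theta/phi.

    Normalised by fixing phi = 1 (valid under CRS homogeneity; under VRS
    the convexity constraint is carried along explicitly via an outer
    bisection on the ratio).  Returns NaN when infeasible.
    """
    x, y, u, ref = _prep(x, y, u, k, exclude_self)
    m, s, q = x.shape[0], y.shape[0], u.shape[0]
    nref = len(ref)
    if returns_to_scale == "CRS":
        # vars: [theta, lambda_ref]; phi = 1
        c = np.zeros(1 + nref)
        c[0] = 1.0
        A_ub, b_ub = [], []
        for i in range(m):
            row = np.zeros(1 + nref)
            row[0] = -x[i, k]
            row[1:] = x[i, ref]
            A_ub.append(row); b_ub.append(0.0)
        for r in range(s):
            row = np.zeros(1 + nref)
            row[1:] = -y[r, ref]
            A_ub.append(row); b_ub.append(-y[r, k])
        for p in range(q):
            row = np.zeros(1 + nref)
            row[1:] = u[p, ref]
            A_ub.append(row); b_ub.append(u[p, k])
        res = linprog(c, A_ub=np.asarray(A_ub), b_ub=np.asarray(b_ub),
                      bounds=[(0, None)] * (1 + nref), method="highs")
        return float(res.fun) if res.success else np.nan

    # VRS: bisection on gamma = theta/phi; feasibility LP at each gamma
    def feasible(gamma: float) -> bool:
        # vars: [phi, lambda_ref]; theta = gamma * phi
        A_ub, b_ub = [], []
        for i in range(m):
            row = np.zeros(1 + nref)
            row[0] = -gamma * x[i, k]
            row[1:] = x[i, ref]
            A_ub.append(row); b_ub.append(0.0)
        for r in range(s):
            row = np.zeros(1 + nref)
            row[0] = y[r, k]
            row[1:] = -y[r, ref]
            A_ub.append(row); b_ub.append(0.0)
        for p in range(q):
            row = np.zeros(1 + nref)
            row[0] = -u[p, k]
            row[1:] = u[p, ref]
            A_ub.append(row); b_ub.append(0.0)
        A_eq = np.zeros((1, 1 + nref)); A_eq[0, 1:] = 1.0
        res = linprog(np.zeros(1 + nref), A_ub=np.asarray(A_ub),
                      b_ub=np.asarray(b_ub), A_eq=A_eq, b_eq=[1.0],
                      bounds=[(1e-9, None)] + [(0, None)] * nref, method="highs")
        return res.success

    lo, hi = 1e-6, 64.0
    if not feasible(hi):
        return np.nan
    while feasible(lo):
        lo /= 4
        if lo < 1e-12:
            return 0.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if feasible(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def sbm_score(x, y, u, k, w_in=None, w_out=None, w_bad=None,
              exclude_self=False, returns_to_scale="CRS", tol=1e-12):
    """Weighted slacks-based measure via Dinkelbach's parametric algorithm.

    Minimises (1 - sum w- s-/x_k) / (1 + sum w+ s+/y_k + sum w_u s_u/u_k)
    by iterating LPs of the form min N(s) - q D(s).  Default weights are
    uniform within each side.  Returns NaN when infeasible.
    """
    x, y, u, ref = _prep(x, y, u, k, exclude_self)
    m, s, q_ = x.shape[0], y.shape[0], u.shape[0]
    nref = len(ref)
    w_in = np.full(m, 1.0 / m) if w_in is None else np.asarray(w_in, float)
    n_out = s + q_
    if w_out is None and w_bad is None:
        w_out = np.full(s, 1.0 / n_out)
        w_bad = np.full(q_, 1.0 / n_out)
    xk, yk, uk = x[:, k], y[:, k], u[:, k]

    # vars: [lambda_ref, sx, sy, su]
    iSx, iSy, iSu = nref, nref + m, nref + m + s
    nv = nref + m + s + q_
    A_eq, b_eq = [], []
    for i in range(m):
        row = np.zeros(nv); row[:nref] = x[i, ref]; row[iSx + i] = 1.0
        A_eq.append(row); b_eq.append(xk[i])
    for r in range(s):
        row = np.zeros(nv); row[:nref] = y[r, ref]; row[iSy + r] = -1.0
        A_eq.append(row); b_eq.append(yk[r])
    for p in range(q_):
        row = np.zeros(nv); row[:nref] = u[p, ref]; row[iSu + p] = 1.0
        A_eq.append(row); b_eq.append(uk[p])
    if returns_to_scale == "VRS":
        row = np.zeros(nv); row[:nref] = 1.0
        A_eq.append(row); b_eq.append(1.0)
    A_eq, b_eq = np.asarray(A_eq), np.asarray(b_eq)

    cn = np.zeros(nv)
    cn[iSx:iSx + m] = -w_in / xk           # N(s) = 1 + cn.s
    cd = np.zeros(nv)
    cd[iSy:iSy + s] = w_out / yk           # D(s) = 1 + cd.s
    cd[iSu:iSu + q_] = w_bad / uk

    q_val = 1.0
    for _ in range(100):
        res = linprog(cn - q_val * cd, A_eq=A_eq, b_eq=b_eq,
                      bounds=[(0, None)] * nv, method="highs")
        if not res.success:
            return np.nan
        num = 1.0 + cn @ res.x
        den = 1.0 + cd @ res.x
        new_q = num / den
        if abs(num - q_val * den) < tol:
            return float(new_q)
        q_val = new_q
    return float(q_val)


def brute_force_ebm(x, y, u, k, params, exclude_self=True,
                    grid=60, refine=6):
    """Grid/LP enumeration of the EBM ratio for tiny instances.

    For each (theta, phi) on a shrinking grid the slack-and-lambda polytope
    is searched with an LP that minimises the ratio's numerator while
    maximising its denominator (both linear once theta and phi are fixed:
    the inner objective min [theta - e- w.sx/xk] - g [phi + e+ w.sy/yk + ...]
    is scanned over candidate ratios g).  Intended only for n <= 3 checks.
    """
    x, y, u, refidx = _prep(x, y, u, k, exclude_self)
    m, s, q_ = x.shape[0], y.shape[0], u.shape[0]
    nref = len(refidx)
    xk, yk, uk = x[:, k], y[:, k], u[:, k]
    ei, eo = params.epsilon_in, params.epsilon_out

    def inner_best(theta, phi, g):
        """min over slacks of numerator - g * denominator at fixed radials."""
        nv = nref + m + s + q_
        iSx, iSy, iSu = nref, nref + m, nref + m + s
        A_eq, b_eq = [], []
        for i in range(m):
            row = np.zeros(nv); row[:nref] = x[i, refidx]; row[iSx + i] = 1.0
            A_eq.append(row); b_eq.append(theta * xk[i])
        for r in range(s):
            row = np.zeros(nv); row[:nref] = y[r, refidx]; row[iSy + r] = -1.0
            A_eq.append(row); b_eq.append(phi * yk[r])
        for p in range(q_):
            row = np.zeros(nv); row[:nref] = u[p, refidx]; row[iSu + p] = 1.0
            A_eq.append(row); b_eq.append(phi * uk[p])
        if params.returns_to_scale == "VRS":
            row = np.zeros(nv); row[:nref] = 1.0
            A_eq.append(row); b_eq.append(1.0)
        c = np.zeros(nv)
        c[iSx:iSx + m] = -ei * params.w_in / xk
        c[iSy:iSy + s] = -g * eo * params.w_out / yk
        c[iSu:iSu + q_] = -g * eo * params.w_bad / uk
        res = linprog(c, A_eq=np.asarray(A_eq), b_eq=np.asarray(b_eq),
                      bounds=[(0, None)] * nv, method="highs")
        if not res.success:
            return None
        num = theta - ei * params.w_in / xk @ res.x[iSx:iSx + m]
        den = (phi + eo * (params.w_out / yk @ res.x[iSy:iSy + s]
                           + params.w_bad / uk @ res.x[iSu:iSu + q_]))
        return num / den

    def scan(t_lo, t_hi, p_lo, p_hi, g_best):
        best = g_best
        arg = None
        for theta in np.linspace(t_lo, t_hi, grid):
            for phi in np.linspace(p_lo, p_hi, grid):
                if phi <= 1e-9 or theta <= 1e-9:
                    continue
                val = inner_best(theta, phi, best if np.isfinite(best) else 1.0)
                if val is not None and val < best:
                    best = val
                    arg = (theta, phi)
        return best, arg

    best = np.inf
    t_lo, t_hi, p_lo, p_hi = 1e-3, 8.0, 1e-3, 8.0
    arg = None
    for _ in range(refine):
        best, new_arg = scan(t_lo, t_hi, p_lo, p_hi, best)
        if new_arg is None:
            if arg is None:
                return np.nan
            new_arg = arg
        arg = new_arg
        dt = (t_hi - t_lo) / grid * 2
        dp = (p_hi - p_lo) / grid * 2
        t_lo, t_hi = max(1e-4, arg[0] - dt), arg[0] + dt
        p_lo, p_hi = max(1e-4, arg[1] - dp), arg[1] + dp
    return float(best)
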