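"""Super-efficiency epsilon-based-measure (EBM) DEA with undesirable outputs.

The EBM score blends a radial contraction/expansion pair (theta, phi) with
weighted non-radial slacks; the key parameter epsilon in [0, 1] sets the
weight of the non-radial part.  epsilon = 0 collapses the model to the
non-oriented radial measure; pinning theta = phi = 1 with epsilon = 1
collapses it to the slacks-based measure (SBM).  Undesirable outputs
(waste, mortality) enter the output side with credit for reduction, and
each unit is scored against a frontier that excludes the unit itself
(super-efficiency), so efficient units can score above 1.

The fractional program is linearised exactly with the Charnes-Cooper
transform and solved with HiGHS via :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel import DEAPanel, EfficiencyTable

__all__ = [
    "EBMParams",
    "EfficiencyResult",
    "determine_epsilon_weights",
    "solve_ebm_super",
    "score_panel",
    "decompose_efficiency",
    "decompose_panel",
    "diversity_index",
    "affinity_matrix",
]

log = logging.getLogger(__name__)

_SOLVER_TOL = 1e-9


@dataclass
class EBMParams:
    """EBM configuration: epsilon values, slack weights, returns to scale.

    ``w_in`` sums to 1 over the m inputs; ``w_out`` (desirable) and
    ``w_bad`` (undesirable) jointly sum to 1 over the s + q outputs.
    """

    epsilon_in: float
    epsilon_out: float
    w_in: np.ndarray
    w_out: np.ndarray
    w_bad: np.ndarray
    returns_to_scale: str = "CRS"

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        self.w_bad = np.asarray(self.w_bad, dtype=float)
        for name, e in (("epsilon_in", self.epsilon_in), ("epsilon_out", self.epsilon_out)):
            if not 0.0 <= e <= 1.0 + 1e-12:
                raise ValueError(f"{name} must lie in [0, 1], got {e}")
        if np.any(self.w_in < 0) or np.any(self.w_out < 0) or np.any(self.w_bad < 0):
            raise ValueError("slack weights must be nonnegative")
        if abs(self.w_in.sum() - 1.0) > 1e-8:
            raise ValueError("input weights must sum to 1")
        if abs(self.w_out.sum() + self.w_bad.sum() - 1.0) > 1e-8:
            raise ValueError("output weights (desirable + undesirable) must sum to 1")
        if self.returns_to_scale not in {"CRS", "VRS"}:
            raise ValueError("returns_to_scale must be CRS or VRS")


@dataclass
class EfficiencyResult:
    """Solution of one EBM program for one evaluated unit."""

    gamma_star: float
    theta: float
    phi: float
    slacks_in: np.ndarray
    slacks_out: np.ndarray
    slacks_bad: np.ndarray
    lambdas: np.ndarray
    feasible: bool
    message: str = ""


def diversity_index(a: np.ndarray, b: np.ndarray) -> float:
    """Diversity of two strictly positive series, in [0, 1/2].

    Based on the spread of the log ratios d_j = ln(a_j / b_j):
    D = sum|d_j - dbar| / (n (d_max - d_min)), 0 for proportional series.
    Symmetric in its arguments.
    """
    d = np.log(np.asarray(a, float)) - np.log(np.asarray(b, float))
    span = d.max() - d.min()
    # proportional series leave only float noise in the log ratios
    if span <= 1e-9 * max(1.0, np.abs(d).max()):
        return 0.0
    return float(np.abs(d - d.mean()).sum() / (len(d) * span))


def affinity_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise affinity S = 1 - 2 D between the rows of a positive matrix."""
    m = rows.shape[0]
    S = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            S[i, j] = S[j, i] = 1.0 - 2.0 * diversity_index(rows[i], rows[j])
    return S


def _weights_and_epsilon(rows: np.ndarray) -> tuple[np.ndarray, float]:
    m = rows.shape[0]
    if m == 1:
        return np.array([1.0]), 0.0
    S = affinity_matrix(rows)
    vals, vecs = np.linalg.eigh(S)
    w = np.abs(vecs[:, -1])
    w = w / w.sum()
    eps = (m - vals[-1]) / (m - 1)
    return w, float(np.clip(eps, 0.0, 1.0))


def determine_epsilon_weights(
    x: np.ndarray, y: np.ndarray, u: np.ndarray, returns_to_scale: str = "CRS"
) -> EBMParams:
    """Derive epsilon and slack weights from the data's diversity structure.

    Rows that are near-proportional across units carry no independent
    non-radial information, so epsilon shrinks toward 0 (pure radial);
    heterogeneous rows push epsilon toward 1.  Weights come from the
    principal eigenvector of the pairwise affinity matrix, computed
    separately for the input side and the combined (desirable +
    undesirable) output side.
    """
    x, y, u = (np.asarray(a, float) for a in (x, y, u))
    if x.shape[1] < 2:
        raise ValueError("need at least two units to determine weights")
    w_in, eps_in = _weights_and_epsilon(x)
    out_rows = np.vstack([y, u])
    w_all, eps_out = _weights_and_epsilon(out_rows)
    s = y.shape[0]
    return EBMParams(
        epsilon_in=eps_in,
        epsilon_out=eps_out,
        w_in=w_in,
        w_out=w_all[:s],
        w_bad=w_all[s:],
        returns_to_scale=returns_to_scale,
    )


def solve_ebm_super(
    x: np.ndarray,
    y: np.ndarray,
    u: np.ndarray,
    k: int,
    params: EBMParams,
    exclude_self: bool = True,
    fix_radial: bool = False,
) -> EfficiencyResult:
    """Solve the non-oriented EBM program for unit ``k`` of a cross-section.

    ``x`` (m, n), ``y`` (s, n), ``u`` (q, n) hold the cross-section;
    ``exclude_self`` drops unit k from its own reference set
    (super-efficiency).  ``fix_radial`` pins theta = phi = 1, which with
    epsilon = 1 reproduces the slacks-based measure.

    Charnes-Cooper variables: [t, Theta, Phi, Lambda_j..., Sx_i..., Sy_r...,
    Su_p...], all nonnegative, with the denominator scaled to 1.  The
    optimum objective value is the efficiency score gamma*.
    """
    x, y, u = (np.atleast_2d(np.asarray(a, float)) for a in (x, y, u))
    m, n = x.shape
    s, q = y.shape[0], u.shape[0]
    if not (0 <= k < n):
        raise IndexError(f"unit index {k} out of range for n={n}")
    ref = [j for j in range(n) if j != k] if exclude_self else list(range(n))
    nref = len(ref)
    xk, yk, uk = x[:, k], y[:, k], u[:, k]
    ei, eo = params.epsilon_in, params.epsilon_out

    # column offsets
    iT, iTh, iPh = 0, 1, 2
    iL = 3
    iSx = iL + nref
    iSy = iSx + m
    iSu = iSy + s
    nv = iSu + q

    c = np.zeros(nv)
    c[iT if fix_radial else iTh] = 1.0
    c[iSx:iSx + m] = -ei * params.w_in / xk

    A_eq, b_eq = [], []
    # denominator normalisation
    row = np.zeros(nv)
    row[iT if fix_radial else iPh] = 1.0
    if s:
        row[iSy:iSy + s] = eo * params.w_out / yk
    if q:
        row[iSu:iSu + q] = eo * params.w_bad / uk
    A_eq.append(row)
    b_eq.append(1.0)
    # inputs: sum_j L_j x_ij + Sx_i - Theta x_ik = 0
    for i in range(m):
        row = np.zeros(nv)
        row[iL:iL + nref] = x[i, ref]
        row[iSx + i] = 1.0
        row[iT if fix_radial else iTh] = -xk[i]
        A_eq.append(row)
        b_eq.append(0.0)
    # desirable outputs: sum_j L_j y_rj - Sy_r - Phi y_rk = 0
    for r in range(s):
        row = np.zeros(nv)
        row[iL:iL + nref] = y[r, ref]
        row[iSy + r] = -1.0
        row[iT if fix_radial else iPh] = -yk[r]
        A_eq.append(row)
        b_eq.append(0.0)
    # undesirable outputs: sum_j L_j u_pj + Su_p - Phi u_pk = 0
    for p in range(q):
        row = np.zeros(nv)
        row[iL:iL + nref] = u[p, ref]
        row[iSu + p] = 1.0
        row[iT if fix_radial else iPh] = -uk[p]
        A_eq.append(row)
        b_eq.append(0.0)
    vrs = params.returns_to_scale == "VRS"
    if vrs:
        row = np.zeros(nv)
        row[iL:iL + nref] = 1.0
        row[iT] = -1.0
        A_eq.append(row)
        b_eq.append(0.0)

    res = linprog(
        c,
        A_eq=np.asarray(A_eq),
        b_eq=np.asarray(b_eq),
        bounds=[(0, None)] * nv,
        method="highs",
        options={"primal_feasibility_tolerance": _SOLVER_TOL,
                 "dual_feasibility_tolerance": _SOLVER_TOL},
    )
    if not res.success:
        log.info("EBM LP infeasible for unit %d (%s)", k, res.message)
        return EfficiencyResult(
            gamma_star=np.nan, theta=np.nan, phi=np.nan,
            slacks_in=np.full(m, np.nan), slacks_out=np.full(s, np.nan),
            slacks_bad=np.full(q, np.nan),
            lambdas=np.full(n, np.nan), feasible=False, message=res.message,
        )
    z = res.x
    t = z[iT]
    # undo the Charnes-Cooper scaling when t is pinned by a constraint;
    # otherwise the denominator-1 representative is reported as-is
    scale = t if (vrs or fix_radial) and t > _SOLVER_TOL else 1.0
    lambdas = np.zeros(n)
    lambdas[ref] = z[iL:iL + nref] / scale
    theta = (t if fix_radial else z[iTh]) / scale
    phi = (t if fix_radial else z[iPh]) / scale
    return EfficiencyResult(
        gamma_star=float(res.fun),
        theta=float(theta),
        phi=float(phi),
        slacks_in=z[iSx:iSx + m] / scale,
        slacks_out=z[iSy:iSy + s] / scale,
        slacks_bad=z[iSu:iSu + q] / scale,
        lambdas=lambdas,
        feasible=True,
    )


def score_panel(
    panel: DEAPanel,
    params: EBMParams | None = None,
    exclude_self: bool = True,
    returns_to_scale: str = "CRS",
) -> EfficiencyTable:
    """Score every unit-year with one cross-sectional frontier per year.

    When ``params`` is None the epsilon/weight configuration is determined
    from each year's cross-section; otherwise the supplied parameters are
    used for every year.
    """
    grid = pd.DataFrame(index=panel.unit_ids, columns=panel.years, dtype=float)
    for t, yr in enumerate(panel.years):
        x, y, u = panel.x[t], panel.y[t], panel.u[t]
        p = params
        if p is None:
            p = determine_epsilon_weights(x, y, u, returns_to_scale)
        elif p.returns_to_scale != returns_to_scale:
            p = EBMParams(p.epsilon_in, p.epsilon_out, p.w_in, p.w_out, p.w_bad,
                          returns_to_scale)
        for k in range(panel.n_units):
            r = solve_ebm_super(x, y, u, k, p, exclude_self=exclude_self)
            grid.iloc[k, t] = r.gamma_star if r.feasible else np.nan
    return EfficiencyTable(scores=grid)


def decompose_efficiency(te_crs: float, te_vrs: float) -> float:
    """Scale efficiency SE = TE / PTE from CRS and VRS scores."""
    te = np.asarray(te_crs, float)
    pte = np.asarray(te_vrs, float)
    if np.any(pte <= 0) or np.any(te <= 0):
        raise ValueError("TE and PTE must be strictly positive")
    out = te / pte
    return float(out) if out.ndim == 0 else out


def decompose_panel(panel: DEAPanel, params: EBMParams | None = None) -> EfficiencyTable:
    """TE / PTE / SE grids from full-reference CRS and VRS runs.

    The decomposition deliberately uses the standard (non-super) models so
    that the CRS frontier envelops the VRS frontier and TE <= PTE holds by
    construction; SE = TE / PTE.
    """
    te = score_panel(panel, params, exclude_self=False, returns_to_scale="CRS")
    pte = score_panel(panel, params, exclude_self=False, returns_to_scale="VRS")
    se = te.scores / pte.scores
    return EfficiencyTable(scores=te.scores, te=te.scores, pte=pte.scores, se=se)
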