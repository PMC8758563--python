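"""Spatial panel econometrics: diagnostics, ML estimation, effect decomposition.

Implements the model-selection chain used for the efficiency regressions:
Harris-Tzavalis unit-root screening for short panels (T < N), Lagrange
multiplier tests for spatial lag/error dependence on OLS residuals, a
Hausman fixed-vs-random effects test, maximum-likelihood estimation of the
spatial lag (SLM), spatial error (SEM) and spatial Durbin (SDM) models
with within-transformed fixed effects, likelihood-ratio / Wald degeneracy
tests of the SDM against SEM and SLM, and the LeSage-Pace direct/indirect
effect decomposition with simulation-based inference.

Panels are passed as arrays ``y`` of shape (T, n) and ``X`` of shape
(T, n, k); the spatial weight matrix is applied within each period.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .weights import SpatialWeightMatrix

__all__ = [
    "SpatialPanelFit",
    "EffectDecomposition",
    "DiagnosticReport",
    "ht_unit_root",
    "lm_diagnostics",
    "fit_spatial_panel",
    "fit_panel_fe",
    "fit_panel_re",
    "hausman_test",
    "lr_wald_degeneracy",
    "decompose_effects",
    "select_model",
]


# --------------------------------------------------------------------------
# containers

@dataclass
class SpatialPanelFit:
    model: str                      # OLS | SLM | SEM | SDM
    effects: str                    # none | time | individual | twoway | random
    beta: np.ndarray
    sigma2: float
    loglik: float
    r2: float
    rho: float | None = None        # spatial lag coefficient
    lambda_err: float | None = None  # spatial error coefficient
    theta_durbin: np.ndarray | None = None
    cov: np.ndarray | None = None   # over [beta, (theta), (rho|lambda)]
    param_names: list[str] = field(default_factory=list)
    nobs: int = 0
    converged: bool = True

    def summary_frame(self) -> pd.DataFrame:
        est = list(self.beta)
        if self.theta_durbin is not None:
            est += list(self.theta_durbin)
        if self.rho is not None:
            est.append(self.rho)
        if self.lambda_err is not None:
            est.append(self.lambda_err)
        est = np.asarray(est)
        se = np.sqrt(np.diag(self.cov)) if self.cov is not None else np.full(len(est), np.nan)
        z = est / se
        return pd.DataFrame(
            {"coef": est, "se": se, "z": z, "p": 2 * stats.norm.sf(np.abs(z))},
            index=self.param_names,
        )


@dataclass
class EffectDecomposition:
    names: list[str]
    direct: np.ndarray
    indirect: np.ndarray
    total: np.ndarray
    direct_se: np.ndarray | None = None
    indirect_se: np.ndarray | None = None
    total_se: np.ndarray | None = None
    n_draws: int = 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"direct": self.direct, "indirect": self.indirect, "total": self.total},
            index=self.names,
        )
        if self.direct_se is not None:
            for part in ("direct", "indirect", "total"):
                se = getattr(self, f"{part}_se")
                df[f"{part}_se"] = se
                z = df[part] / se
                df[f"{part}_p"] = 2 * stats.norm.sf(np.abs(z))
        return df


@dataclass
class DiagnosticReport:
    ht: pd.DataFrame | None = None
    lm: dict | None = None
    hausman: tuple | None = None            # (statistic, df, p)
    lr_wald: pd.DataFrame | None = None
    r2_by_effects: dict | None = None
    chosen: dict | None = None


# --------------------------------------------------------------------------
# transformations

def _demean(a: np.ndarray, effects: str) -> np.ndarray:
    """Within transformation on a (T, n) or (T, n, k) panel array."""
    if effects in ("none", "random"):
        return a
    out = a.astype(float).copy()
    if effects in ("time", "twoway"):
        out = out - out.mean(axis=1, keepdims=True)
    if effects in ("individual", "twoway"):
        # sequential demeaning equals the two-way within transform
        out = out - out.mean(axis=0, keepdims=True)
    return out


def _stack(a: np.ndarray) -> np.ndarray:
    """(T, n) -> (T*n,) or (T, n, k) -> (T*n, k), period-major."""
    if a.ndim == 2:
        return a.reshape(-1)
    return a.reshape(-1, a.shape[2])


def _apply_w(a: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Spatial lag per period: (T, n[, k]) -> same shape."""
    if a.ndim == 2:
        return np.einsum("ij,tj->ti", w, a)
    return np.einsum("ij,tjk->tik", w, a)


def _check_panel(y: np.ndarray, X: np.ndarray, W: SpatialWeightMatrix):
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 2:
        raise ValueError("y must be (T, n)")
    T, n = y.shape
    if X.shape[:2] != (T, n) or X.ndim != 3:
        raise ValueError("X must be (T, n, k) aligned with y")
    if n != W.n:
        raise ValueError("weight matrix size does not match panel width")
    if W.standardized != "row":
        raise ValueError("W must be row-standardised")
    return y, X


def _rho_interval(w: np.ndarray) -> tuple[float, float, np.ndarray]:
    omega = np.linalg.eigvals(w)
    if np.abs(omega.imag).max() > 1e-8:
        # similarity to a symmetric matrix fails only for exotic W
        omega = omega[np.abs(omega.imag) < 1e-8]
    omega = np.sort(omega.real)
    lo = 1.0 / omega[0] if omega[0] < -1e-12 else -1.0
    hi = 1.0 / omega[-1] if omega[-1] > 1e-12 else 1.0
    return lo + 1e-6, hi - 1e-6, omega


# --------------------------------------------------------------------------
# HT unit-root test

def ht_unit_root(panel: np.ndarray, demean: bool = True):
    """Harris-Tzavalis unit-root test for short balanced panels.

    ``panel`` has shape (N, T+1): N units observed at T+1 time points,
    giving T usable lagged regressions per unit.  The pooled (LSDV when
    ``demean``) AR(1) estimate is compared with its exact null expectation
    under a random walk — 1 - 3/(T+1) with unit intercepts — and the
    normalised deviate is asymptotically standard normal in N.

    Returns ``(statistic, z, p)`` where statistic is the pooled AR(1)
    estimate and p is the left-tail probability (small p rejects the
    unit root).
    """
    a = np.asarray(panel, dtype=float)
    if a.ndim != 2:
        raise ValueError("panel must be (N, T+1)")
    if not np.all(np.isfinite(a)):
        raise ValueError("panel must be balanced with no missing cells")
    N, Tp1 = a.shape
    T = Tp1 - 1
    if T < 2:
        raise ValueError("need at least 3 time points (T >= 2 transitions)")
    y_t = a[:, 1:]
    y_l = a[:, :-1]
    if demean:
        y_t = y_t - y_t.mean(axis=1, keepdims=True)
        y_l = y_l - y_l.mean(axis=1, keepdims=True)
        B = 1.0 - 3.0 / (T + 1)
        C = 3.0 * (17 * T ** 2 - 20 * T + 17) / (5.0 * (T - 1) * (T + 1) ** 3)
    else:
        B = 1.0
        C = 2.0 / (T * (T + 1))
    rho_hat = float((y_l * y_t).sum() / (y_l * y_l).sum())
    z = np.sqrt(N) * (rho_hat - B) / np.sqrt(C)
    p = float(stats.norm.cdf(z))
    return rho_hat, float(z), p


# --------------------------------------------------------------------------
# OLS helpers and LM diagnostics

def _ols(ys: np.ndarray, Zs: np.ndarray):
    coef, *_ = np.linalg.lstsq(Zs, ys, rcond=None)
    resid = ys - Zs @ coef
    return coef, resid


def lm_diagnostics(y, X, W: SpatialWeightMatrix, effects: str = "none") -> dict:
    """Anselin LM and robust LM score tests on (within-transformed) OLS residuals.

    Returns a dict with lm_lag, lm_error, rlm_lag, rlm_error, each a
    (statistic, p) pair against chi-square(1).
    """
    y, X = _check_panel(y, X, W)
    T, n, k = X.shape
    yd, Xd = _demean(y, effects), _demean(X, effects)
    ys, Zs = _stack(yd), _stack(Xd)
    if np.linalg.matrix_rank(Zs) < Zs.shape[1]:
        raise np.linalg.LinAlgError("covariate matrix is singular")
    coef, e = _ols(ys, Zs)
    NT = T * n
    sigma2 = float(e @ e) / NT

    w = W.w
    Wy = _stack(_apply_w(yd, w))
    We = _stack(_apply_w(e.reshape(T, n), w))
    d_y = float(e @ Wy) / sigma2
    R = float(e @ We) / sigma2
    Tw = T * float(np.trace(w.T @ w + w @ w))
    g = _stack(_apply_w((Xd @ coef), w))
    Mg = g - Zs @ np.linalg.lstsq(Zs, g, rcond=None)[0]
    D = float(g @ Mg) / sigma2
    J = D + Tw

    lm_lag = d_y ** 2 / J
    lm_err = R ** 2 / Tw
    rlm_lag = (d_y - R) ** 2 / D if D > 0 else 0.0
    denom = Tw * (1.0 - Tw / J)
    rlm_err = (R - (Tw / J) * d_y) ** 2 / denom if denom > 0 else 0.0

    chi2 = stats.chi2(df=1)
    return {
        name: (float(val), float(chi2.sf(val)))
        for name, val in [
            ("lm_lag", lm_lag), ("lm_error", lm_err),
            ("rlm_lag", rlm_lag), ("rlm_error", rlm_err),
        ]
    }


# --------------------------------------------------------------------------
# non-spatial panel estimators (Hausman arm)

def fit_panel_fe(y, X) -> SpatialPanelFit:
    """Within (fixed-effects) OLS with conventional covariance."""
    y = np.asarray(y, float); X = np.asarray(X, float)
    T, n, k = X.shape
    yd, Xd = _demean(y, "individual"), _demean(X, "individual")
    ys, Zs = _stack(yd), _stack(Xd)
    coef, e = _ols(ys, Zs)
    dof = T * n - n - k
    sigma2 = float(e @ e) / dof
    cov = sigma2 * np.linalg.inv(Zs.T @ Zs)
    ss_res = float(e @ e)
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    return SpatialPanelFit(
        model="OLS", effects="individual", beta=coef, sigma2=sigma2,
        loglik=np.nan, r2=1 - ss_res / ss_tot, cov=cov,
        param_names=[f"x{i}" for i in range(k)], nobs=T * n,
    )


def fit_panel_re(y, X) -> SpatialPanelFit:
    """Random-effects GLS with Swamy-Arora variance components.

    The idiosyncratic variance comes from the within residuals and the
    unit-effect variance from the between regression on unit means.
    """
    y = np.asarray(y, float); X = np.asarray(X, float)
    T, n, k = X.shape
    fe = fit_panel_fe(y, X)
    sigma_e2 = fe.sigma2
    # between regression on unit means (with intercept)
    yb = y.mean(axis=0)
    Xb = np.column_stack([np.ones(n), X.mean(axis=0)])
    coef_b, e_b = _ols(yb, Xb)
    sigma_b2 = float(e_b @ e_b) / max(n - k - 1, 1)
    sigma_a2 = max(sigma_b2 - sigma_e2 / T, 0.0)
    theta = 1.0 - np.sqrt(sigma_e2 / (sigma_e2 + T * sigma_a2))
    # quasi-demeaning
    yq = y - theta * y.mean(axis=0, keepdims=True)
    Xq = X - theta * X.mean(axis=0, keepdims=True)
    ones = np.ones((T, n, 1)) * (1.0 - theta)
    Zq = _stack(np.concatenate([ones, Xq], axis=2))
    ys = _stack(yq)
    coef, e = _ols(ys, Zq)
    sigma2 = float(e @ e) / (T * n - k - 1)
    cov = sigma2 * np.linalg.inv(Zq.T @ Zq)
    return SpatialPanelFit(
        model="OLS", effects="random", beta=coef[1:], sigma2=sigma2,
        loglik=np.nan, r2=np.nan, cov=cov[1:, 1:],
        param_names=[f"x{i}" for i in range(k)], nobs=T * n,
    )


def hausman_test(fit_fe: SpatialPanelFit, fit_re: SpatialPanelFit):
    """Hausman specification test on the common coefficient subset.

    H = d' (V_fe - V_re)^+ d with d the coefficient difference; the
    Moore-Penrose inverse is used when the covariance difference is not
    positive definite.  Returns (statistic, df, p).
    """
    common = [nm for nm in fit_fe.param_names if nm in fit_re.param_names]
    if not common:
        raise ValueError("fits share no coefficients")
    ia = [fit_fe.param_names.index(nm) for nm in common]
    ib = [fit_re.param_names.index(nm) for nm in common]
    d = fit_fe.beta[ia] - fit_re.beta[ib]
    V = fit_fe.cov[np.ix_(ia, ia)] - fit_re.cov[np.ix_(ib, ib)]
    try:
        L = np.linalg.cholesky(V)
        sol = np.linalg.solve(L, d)
        stat = float(sol @ sol)
    except np.linalg.LinAlgError:
        stat = float(d @ np.linalg.pinv(V) @ d)
    stat = max(stat, 0.0)
    df = len(common)
    return stat, df, float(stats.chi2(df).sf(stat))


# --------------------------------------------------------------------------
# spatial maximum likelihood

def _loglik_lag(rho, e0, e1, omega, T, NT):
    sse = float((e0 - rho * e1) @ (e0 - rho * e1))
    logdet = T * float(np.log(1.0 - rho * omega).sum())
    return -0.5 * NT * (np.log(2 * np.pi) + 1.0) - 0.5 * NT * np.log(sse / NT) + logdet


def fit_spatial_panel(
    y, X, W: SpatialWeightMatrix, model: str = "SDM", effects: str = "time",
) -> SpatialPanelFit:
    """Maximum-likelihood fit of OLS/SLM/SEM/SDM with fixed effects.

    The spatial coefficient is found by concentrating the log-likelihood,
    with the log-determinant computed exactly from the eigenvalues of W
    (n is small).  SDM regressors are [X, WX].  The reported R^2 is the
    squared correlation between observed and (reduced-form) fitted values
    on the transformed data; the covariance matrix over
    [beta, (theta), (rho|lambda)] comes from the numerical Hessian of the
    full log-likelihood.
    """
    y, X = _check_panel(y, X, W)
    T, n, k = X.shape
    w = W.w
    yd = _demean(y, effects)
    Xd = _demean(X, effects)
    if model in ("SDM",):
        Zd = np.concatenate([Xd, _demean(_apply_w(X, w), effects)], axis=2)
    else:
        Zd = Xd
    kz = Zd.shape[2]
    ys, Zs = _stack(yd), _stack(Zd)
    # degrees of freedom and Jacobian of the within transformation:
    # cross-sectional demeaning annihilates W's unit eigenvector, so one
    # eigenvalue (=1 for row-standardised W) leaves the log-determinant and
    # the effective cross-section shrinks to n-1; time demeaning removes
    # one period (Lee-Yu within-estimator correction)
    n_eff = n - 1 if effects in ("time", "twoway") else n
    T_eff = T - 1 if effects in ("individual", "twoway") else T
    NT = n_eff * T_eff
    names = [f"x{i}" for i in range(k)]
    if model == "SDM":
        names += [f"Wx{i}" for i in range(k)]

    if model == "OLS":
        coef, e = _ols(ys, Zs)
        sigma2 = float(e @ e) / NT
        ll = -0.5 * NT * (np.log(2 * np.pi * sigma2) + 1.0)
        cov = sigma2 * np.linalg.inv(Zs.T @ Zs)
        r2 = _sq_corr(ys, Zs @ coef)
        return SpatialPanelFit(model="OLS", effects=effects, beta=coef,
                               sigma2=sigma2, loglik=ll, r2=r2, cov=cov,
                               param_names=names, nobs=T * n)

    lo, hi, omega = _rho_interval(w)
    if n_eff < n:
        # drop the eigenvalue annihilated by cross-sectional demeaning
        keep = np.ones(len(omega), dtype=bool)
        keep[np.argmin(np.abs(omega - 1.0))] = False
        omega_det = omega[keep]
    else:
        omega_det = omega

    if model in ("SLM", "SDM"):
        Wys = _stack(_demean(_apply_w(yd, w), effects))
        d0, e0 = _ols(ys, Zs)
        d1, e1 = _ols(Wys, Zs)

        res = optimize.minimize_scalar(
            lambda r: -_loglik_lag(r, e0, e1, omega_det, T_eff, NT),
            bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        rho = float(res.x)
        # a flat profile (e.g. W = 0 leaves rho unidentified) collapses to OLS
        if _loglik_lag(0.0, e0, e1, omega_det, T_eff, NT) >= -res.fun - 1e-9:
            rho = 0.0
        converged = res.success and lo + 1e-4 < rho < hi - 1e-4
        coef = d0 - rho * d1
        e = e0 - rho * e1
        sigma2 = float(e @ e) / NT
        ll = _loglik_lag(rho, e0, e1, omega_det, T_eff, NT)

        def negll(p):
            b, r, s2 = p[:kz], p[kz], p[kz + 1]
            if s2 <= 0 or not (lo < r < hi):
                return 1e12  # finite penalty keeps finite differences defined
            resid = ys - r * Wys - Zs @ b
            logdet = T_eff * float(np.log(1.0 - r * omega_det).sum())
            return 0.5 * NT * np.log(2 * np.pi * s2) - logdet + resid @ resid / (2 * s2)

        theta_hat = np.concatenate([coef, [rho, sigma2]])
        cov_full = _hessian_cov(negll, theta_hat)
        cov = cov_full[: kz + 1, : kz + 1]
        # reduced-form fitted values per period
        A = np.linalg.inv(np.eye(n) - rho * w)
        fitted = np.einsum("ij,tj->ti", A, (Zd @ coef))
        r2 = _sq_corr(ys, _stack(fitted))
        beta = coef[:k]
        theta_durbin = coef[k:] if model == "SDM" else None
        return SpatialPanelFit(
            model=model, effects=effects, beta=beta, theta_durbin=theta_durbin,
            rho=rho, sigma2=sigma2, loglik=ll, r2=r2, cov=cov,
            param_names=names + ["rho"], nobs=NT, converged=converged,
        )

    if model == "SEM":
        WZ = _demean(_apply_w(X, w), effects)
        Wys = _stack(_apply_w(yd, w))
        WZs = _stack(WZ)

        def conc(lam):
            By = ys - lam * Wys
            BZ = Zs - lam * WZs
            b, e = _ols(By, BZ)
            sse = float(e @ e)
            logdet = T_eff * float(np.log(1.0 - lam * omega_det).sum())
            return (-0.5 * NT * (np.log(2 * np.pi) + 1.0)
                    - 0.5 * NT * np.log(sse / NT) + logdet), b, e

        res = optimize.minimize_scalar(
            lambda l: -conc(l)[0], bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        lam = float(res.x)
        if conc(0.0)[0] >= -res.fun - 1e-9:
            lam = 0.0
        ll, coef, e = conc(lam)
        sigma2 = float(e @ e) / NT
        converged = res.success and lo + 1e-4 < lam < hi - 1e-4

        def negll(p):
            b, l, s2 = p[:kz], p[kz], p[kz + 1]
            if s2 <= 0 or not (lo < l < hi):
                return 1e12
            resid = (ys - Zs @ b) - l * (Wys - WZs @ b)
            logdet = T_eff * float(np.log(1.0 - l * omega_det).sum())
            return 0.5 * NT * np.log(2 * np.pi * s2) - logdet + resid @ resid / (2 * s2)

        theta_hat = np.concatenate([coef, [lam, sigma2]])
        cov_full = _hessian_cov(negll, theta_hat)
        cov = cov_full[: kz + 1, : kz + 1]
        r2 = _sq_corr(ys, Zs @ coef)
        return SpatialPanelFit(
            model="SEM", effects=effects, beta=coef, lambda_err=lam,
            sigma2=sigma2, loglik=ll, r2=r2, cov=cov,
            param_names=names + ["lambda"], nobs=NT, converged=converged,
        )

    raise ValueError(f"unknown model {model!r}")


def _sq_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def _hessian_cov(f, x0: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Covariance from the numerical Hessian of a negative log-likelihood."""
    p = len(x0)
    h = rel_step * np.maximum(np.abs(x0), 1.0)
    H = np.empty((p, p))
    f0 = f(x0)
    for i in range(p):
        for j in range(i, p):
            xi, xj = np.zeros(p), np.zeros(p)
            xi[i] = h[i]; xj[j] = h[j]
            fpp = f(x0 + xi + xj)
            fpm = f(x0 + xi - xj)
            fmp = f(x0 - xi + xj)
            fmm = f(x0 - xi - xj)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# --------------------------------------------------------------------------
# degeneracy tests and effects

def lr_wald_degeneracy(fit_sdm: SpatialPanelFit, fit_sem: SpatialPanelFit,
                       fit_slm: SpatialPanelFit, tol: float = 1e-6) -> pd.DataFrame:
    """LR and Wald tests of whether the SDM degenerates to SEM or SLM.

    LR = 2(logL_SDM - logL_restricted), df = k.  The Wald test against
    SLM is H0: theta = 0; against SEM it is the common-factor restriction
    H0: theta + rho * beta = 0 (delta method on the SDM covariance).
    """
    k = len(fit_sdm.beta)
    out = {}
    for name, restricted in (("SEM", fit_sem), ("SLM", fit_slm)):
        lr = 2.0 * (fit_sdm.loglik - restricted.loglik)
        if lr < -tol * max(1.0, abs(fit_sdm.loglik)):
            raise RuntimeError(
                f"negative LR vs {name} ({lr:.3g}): restricted fit did not converge")
        lr = max(lr, 0.0)
        out[name] = {"LR": lr, "LR_p": float(stats.chi2(k).sf(lr))}

    beta, theta, rho = fit_sdm.beta, fit_sdm.theta_durbin, fit_sdm.rho
    V = fit_sdm.cov  # over [beta, theta, rho]
    # Wald vs SLM: theta = 0
    Vtt = V[k:2 * k, k:2 * k]
    w_slm = float(theta @ np.linalg.solve(Vtt, theta))
    out["SLM"].update({"Wald": w_slm, "Wald_p": float(stats.chi2(k).sf(w_slm))})
    # Wald vs SEM: theta + rho beta = 0
    g = theta + rho * beta
    G = np.zeros((k, 2 * k + 1))
    G[:, :k] = rho * np.eye(k)
    G[:, k:2 * k] = np.eye(k)
    G[:, 2 * k] = beta
    Vg = G @ V @ G.T
    w_sem = float(g @ np.linalg.solve(Vg, g))
    out["SEM"].update({"Wald": w_sem, "Wald_p": float(stats.chi2(k).sf(w_sem))})
    return pd.DataFrame(out).T[["LR", "LR_p", "Wald", "Wald_p"]]


def decompose_effects(
    fit: SpatialPanelFit, W: SpatialWeightMatrix,
    n_draws: int = 1000, seed: int | None = None,
    names: list[str] | None = None,
) -> EffectDecomposition:
    """LeSage-Pace direct/indirect/total effects of each covariate.

    For covariate k the effects matrix is
    S_k = (I - rho W)^{-1} (I beta_k + W theta_k);
    direct = mean diagonal, total = mean row sum, indirect = total - direct.
    Standard errors come from parameter draws from the estimated sampling
    distribution of (beta, theta, rho).
    """
    if fit.rho is None:
        raise ValueError("effects decomposition needs a spatial-lag fit (SLM/SDM)")
    w = W.w
    n = W.n
    lo, hi, _ = _rho_interval(w)
    if not (lo < fit.rho < hi):
        raise ValueError(f"rho={fit.rho} outside the stable interval ({lo:.3f}, {hi:.3f})")
    k = len(fit.beta)
    theta = fit.theta_durbin if fit.theta_durbin is not None else np.zeros(k)
    names = names or [f"x{i}" for i in range(k)]

    def point(beta_v, theta_v, rho_v):
        A = np.linalg.inv(np.eye(n) - rho_v * w)
        direct = np.empty(k); total = np.empty(k)
        for j in range(k):
            S = A @ (np.eye(n) * beta_v[j] + w * theta_v[j])
            direct[j] = np.trace(S) / n
            total[j] = S.sum() / n
        return direct, total - direct, total

    direct, indirect, total = point(fit.beta, theta, fit.rho)
    d_se = i_se = t_se = None
    if n_draws > 0 and fit.cov is not None:
        rng = np.random.default_rng(seed)
        npar = fit.cov.shape[0]
        mean = np.concatenate([fit.beta, theta, [fit.rho]]) if fit.theta_durbin is not None \
            else np.concatenate([fit.beta, [fit.rho]])
        draws = rng.multivariate_normal(mean, fit.cov, size=n_draws,
                                        method="svd")
        sims = np.empty((n_draws, 3, k))
        kept = 0
        for row in draws:
            if fit.theta_durbin is not None:
                b, th, r = row[:k], row[k:2 * k], row[2 * k]
            else:
                b, th, r = row[:k], np.zeros(k), row[k]
            if not (lo < r < hi):
                continue
            sims[kept] = point(b, th, r)
            kept += 1
        sims = sims[:kept]
        d_se = sims[:, 0, :].std(axis=0, ddof=1)
        i_se = sims[:, 1, :].std(axis=0, ddof=1)
        t_se = sims[:, 2, :].std(axis=0, ddof=1)
    return EffectDecomposition(
        names=names, direct=direct, indirect=indirect, total=total,
        direct_se=d_se, indirect_se=i_se, total_se=t_se, n_draws=n_draws,
    )


# --------------------------------------------------------------------------
# model selection

def select_model(
    y, X, W: SpatialWeightMatrix,
    alpha: float = 0.05,
    covariate_names: list[str] | None = None,
    n_effect_draws: int = 1000,
    seed: int | None = None,
):
    """Diagnostic-driven model selection for the efficiency panel.

    Order: (1) HT stationarity screen per covariate, (2) LM tests on OLS
    residuals — if neither spatial statistic is significant at ``alpha``
    the pooled OLS specification is returned, (3) Hausman fixed-vs-random
    effects, (4) SDM fitted under time/individual/twoway fixed effects and
    the variant with the highest R^2 retained, (5) LR and Wald degeneracy
    tests against SEM and SLM.  Returns (fit, DiagnosticReport).
    """
    y, X = _check_panel(y, X, W)
    T, n, k = X.shape
    names = covariate_names or [f"x{i}" for i in range(k)]

    ht_rows = {}
    for j, nm in enumerate(names):
        stat, z, p = ht_unit_root(X[:, :, j].T, demean=True)
        ht_rows[nm] = {"statistic": stat, "z": z, "p": p}
    ht = pd.DataFrame(ht_rows).T

    lm = lm_diagnostics(y, X, W, effects="none")
    report = DiagnosticReport(ht=ht, lm=lm)
    if lm["lm_lag"][1] >= alpha and lm["lm_error"][1] >= alpha:
        fit = fit_spatial_panel(y, X, W, model="OLS", effects="none")
        report.chosen = {"model": "OLS", "effects": "none"}
        return fit, report

    report.hausman = hausman_test(fit_panel_fe(y, X), fit_panel_re(y, X))
    use_fixed = report.hausman[2] < alpha

    fits = {}
    if use_fixed:
        for eff in ("time", "individual", "twoway"):
            fits[eff] = fit_spatial_panel(y, X, W, model="SDM", effects=eff)
        report.r2_by_effects = {eff: f.r2 for eff, f in fits.items()}
        best_eff = max(fits, key=lambda e: fits[e].r2)
    else:
        best_eff = "none"
        fits["none"] = fit_spatial_panel(y, X, W, model="SDM", effects="none")
        report.r2_by_effects = {"none": fits["none"].r2}
    sdm = fits[best_eff]

    sem = fit_spatial_panel(y, X, W, model="SEM", effects=best_eff)
    slm = fit_spatial_panel(y, X, W, model="SLM", effects=best_eff)
    report.lr_wald = lr_wald_degeneracy(sdm, sem, slm)

    keep_sdm = (report.lr_wald.loc["SEM", "LR_p"] < alpha
                and report.lr_wald.loc["SLM", "LR_p"] < alpha)
    if keep_sdm:
        chosen = sdm
    else:
        # degenerate toward the better-supported restricted model
        chosen = sem if sem.loglik >= slm.loglik else slm
    report.chosen = {"model": chosen.model, "effects": chosen.effects}
    return chosen, report
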