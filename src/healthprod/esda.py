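"""Exploratory spatial data analysis: Moran's I, local quadrants, Getis-Ord Gi*.

Global Moran's I measures whether similar efficiency values cluster in
space (expectation -1/(n-1) under spatial randomness).  Local Moran
quadrants classify each unit by the sign of its own deviation and of its
neighbourhood average's deviation (HH, LH, LL, HL); the Gi* share
statistic flags hot and cold spots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .weights import SpatialWeightMatrix, row_standardize

__all__ = [
    "MoranResult",
    "LocalStats",
    "global_morans_i",
    "moran_inference",
    "local_moran_quadrants",
    "getis_ord_gstar",
]


@dataclass
class MoranResult:
    I: float
    expected: float
    z: float | None = None
    p: float | None = None
    method: str | None = None
    n_perm: int | None = None
    seed: int | None = None


@dataclass
class LocalStats:
    labels: list
    quadrant: list  # per-unit HH/LH/LL/HL
    lag: np.ndarray
    gi_star: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"quadrant": self.quadrant, "lag": self.lag}
        if self.gi_star is not None:
            data["gi_star"] = self.gi_star
        return pd.DataFrame(data, index=self.labels)


def _check(x: np.ndarray, W: SpatialWeightMatrix) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != W.n:
        raise ValueError("x must be one value per unit of W")
    if len(x) < 3:
        raise ValueError("need at least 3 units")
    if np.var(x) == 0:
        raise ValueError("x is constant: Moran statistics are degenerate")
    return x


def _moran_stat(x: np.ndarray, w: np.ndarray) -> float:
    z = x - x.mean()
    num = len(x) * (z @ w @ z)
    den = w.sum() * (z @ z)
    return float(num / den)


def global_morans_i(x, W: SpatialWeightMatrix) -> MoranResult:
    """Global Moran's I cross-product statistic with E[I] = -1/(n-1)."""
    x = _check(x, W)
    n = len(x)
    return MoranResult(I=_moran_stat(x, W.w), expected=-1.0 / (n - 1))


def moran_inference(
    x,
    W: SpatialWeightMatrix,
    method: str = "permutation",
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> MoranResult:
    """Moran's I with a z-score and p-value.

    ``method='normal'`` uses the analytic randomisation variance;
    ``method='permutation'`` relabels x over the units n_perm times and
    reports the pseudo p-value (count(|I_perm| >= |I_obs|)+1)/(n_perm+1)
    for the two-sided variant, one tail counts otherwise.  Both methods
    also report z from the randomisation variance.
    """
    x = _check(x, W)
    n = len(x)
    w = W.w
    I_obs = _moran_stat(x, w)
    e_i = -1.0 / (n - 1)

    # analytic randomisation variance (Cliff-Ord)
    s0 = w.sum()
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    z_dev = x - x.mean()
    m2 = (z_dev ** 2).sum() / n
    m4 = (z_dev ** 4).sum() / n
    b2 = m4 / m2 ** 2
    a = n * ((n ** 2 - 3 * n + 3) * s1 - n * s2 + 3 * s0 ** 2)
    c = b2 * ((n ** 2 - n) * s1 - 2 * n * s2 + 6 * s0 ** 2)
    var = (a - c) / ((n - 1) * (n - 2) * (n - 3) * s0 ** 2) - e_i ** 2
    z_score = (I_obs - e_i) / np.sqrt(var)

    if method == "normal":
        if alternative == "two-sided":
            p = 2 * stats.norm.sf(abs(z_score))
        elif alternative == "greater":
            p = stats.norm.sf(z_score)
        else:
            p = stats.norm.cdf(z_score)
        return MoranResult(I=I_obs, expected=e_i, z=float(z_score), p=float(p),
                           method="normal")
    if method != "permutation":
        raise ValueError("method must be 'normal' or 'permutation'")
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    rng = np.random.default_rng(seed)
    sims = np.empty(n_perm)
    for b in range(n_perm):
        sims[b] = _moran_stat(rng.permutation(x), w)
    if alternative == "two-sided":
        count = np.sum(np.abs(sims - e_i) >= abs(I_obs - e_i))
    elif alternative == "greater":
        count = np.sum(sims >= I_obs)
    else:
        count = np.sum(sims <= I_obs)
    p = (count + 1) / (n_perm + 1)
    return MoranResult(I=I_obs, expected=e_i, z=float(z_score), p=float(p),
                       method="permutation", n_perm=n_perm, seed=seed)


def local_moran_quadrants(x, W: SpatialWeightMatrix, tie: str = "low") -> LocalStats:
    """Moran-scatter quadrant (HH/LH/LL/HL) for every unit.

    The quadrant pairs the sign of the unit's deviation from the mean with
    the sign of its spatial lag's deviation.  Exact zeros are assigned to
    the low side by default (``tie='low'``; set ``tie='high'`` to flip).
    """
    x = _check(x, W)
    if W.standardized != "row":
        W = row_standardize(W)
    lag = W.w @ x
    xbar = x.mean()
    hi_own = (x > xbar) if tie == "low" else (x >= xbar)
    hi_lag = (lag > xbar) if tie == "low" else (lag >= xbar)
    quadrant = [
        ("H" if ho else "L") + ("H" if hl else "L")
        for ho, hl in zip(hi_own, hi_lag)
    ]
    return LocalStats(labels=list(W.labels), quadrant=quadrant, lag=lag)


def getis_ord_gstar(
    x, W_star: SpatialWeightMatrix, standardized: bool = False,
    include_self: bool = True,
) -> np.ndarray:
    """Getis-Ord concentration statistic per unit.

    In ratio form Gi* = sum_j W_ij x_j / sum_j x_j with self-inclusive
    row-standardised weights (``include_self=False`` gives the plain Gi).
    ``standardized=True`` returns the usual z-scored variant instead.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != W_star.n:
        raise ValueError("x must be one value per unit of W")
    if x.sum() == 0:
        raise ValueError("sum of x is zero: ratio statistic undefined")
    w = W_star.w.copy()
    if include_self and np.all(np.diag(w) == 0):
        np.fill_diagonal(w, 1.0)
        sums = w.sum(axis=1)
        w = w / sums[:, None]
    if not standardized:
        return (w @ x) / x.sum()
    # z-scored variant
    n = len(x)
    xbar, s = x.mean(), x.std()
    wsum = w.sum(axis=1)
    w2sum = (w ** 2).sum(axis=1)
    num = w @ x - wsum * xbar
    den = s * np.sqrt((n * w2sum - wsum ** 2) / (n - 1))
    return num / den
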