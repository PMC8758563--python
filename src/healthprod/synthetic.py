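"""Synthetic data generators and the packaged printed-score fixture.

Two generators supply inputs with the statistical structure the analysis
assumes: a log-linear production frontier with half-normal inefficiency
for the DEA stage, and a spatial Durbin data-generating process for the
econometric stage.  Both are pure functions of their spec (seed included).

The packaged fixture is the published 31-province x 11-year efficiency
grid (2009-2019) with its regional labels and printed row summaries; it
drives the regional-aggregation checks without any raw yearbook data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .panel import DEAPanel, EfficiencyTable
from .weights import SpatialWeightMatrix

__all__ = [
    "FrontierSpec",
    "SDMSpec",
    "generate_frontier_panel",
    "generate_sdm_panel",
    "fixture_table3",
]


@dataclass
class FrontierSpec:
    """Configuration of the log-linear frontier generator.

    ``elasticities`` are the frontier exponents of the m inputs (positive);
    ``inefficiency_scale`` is the half-normal sigma of the log-inefficiency
    term; ``bad_coupling`` links undesirable outputs to activity level;
    ``n_frontier`` units are generated with zero inefficiency so the true
    frontier is populated.
    """

    n_units: int = 31
    n_years: int = 11
    m: int = 4
    s: int = 1
    q: int = 2
    elasticities: np.ndarray | None = None
    inefficiency_scale: float = 0.3
    bad_coupling: float = 1.0
    noise_scale: float = 0.05
    n_frontier: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.elasticities is None:
            self.elasticities = np.full(self.m, 0.8 / self.m)
        self.elasticities = np.asarray(self.elasticities, dtype=float)
        if np.any(self.elasticities <= 0):
            raise ValueError("frontier elasticities must be positive")
        if self.inefficiency_scale < 0 or self.noise_scale < 0:
            raise ValueError("scales must be nonnegative")
        if self.n_units < self.m + self.s + self.q + 1:
            import warnings
            warnings.warn(
                "fewer units than inputs+outputs+1: DEA discrimination "
                "will be poor", stacklevel=2)


def generate_frontier_panel(spec: FrontierSpec) -> tuple[DEAPanel, pd.DataFrame]:
    """Draw a DEA panel on a known frontier; returns (panel, true efficiency).

    Inputs are lognormal; the primary desirable output sits on the
    log-linear frontier y = A * prod x_i^a_i scaled down by exp(-v) with v
    half-normal (v = 0 for the designated frontier units); any secondary
    desirable outputs are noisy monotone transforms of the first;
    undesirable outputs are proportional to activity with lognormal noise.
    """
    rng = np.random.default_rng(spec.seed)
    n, T = spec.n_units, spec.n_years
    x = np.exp(rng.normal(0.0, 0.4, size=(T, spec.m, n)) + 1.0)
    ineff = rng.normal(0.0, 1.0, size=(T, n))
    v = np.abs(ineff) * spec.inefficiency_scale
    frontier_units = np.arange(min(spec.n_frontier, n))
    v[:, frontier_units] = 0.0
    true_eff = np.exp(-v)

    frontier = np.exp((spec.elasticities[None, :, None] * np.log(x)).sum(axis=1))
    y = np.empty((T, spec.s, n))
    y[:, 0, :] = frontier * true_eff
    for r in range(1, spec.s):
        jitter = np.exp(rng.normal(0.0, spec.noise_scale, size=(T, n)))
        y[:, r, :] = y[:, 0, :] ** 0.9 * jitter

    activity = x.mean(axis=1)  # (T, n) aggregate input level
    u = np.empty((T, spec.q, n))
    for p in range(spec.q):
        jitter = np.exp(rng.normal(0.0, spec.noise_scale, size=(T, n)))
        # inefficient units emit disproportionately more bad output
        u[:, p, :] = spec.bad_coupling * activity * jitter / true_eff

    units = [f"U{i:02d}" for i in range(n)]
    years = list(range(2009, 2009 + T))
    panel = DEAPanel(unit_ids=units, years=years, x=x, y=y, u=u)
    truth = pd.DataFrame(true_eff.T, index=units, columns=years)
    return panel, truth


@dataclass
class SDMSpec:
    """Configuration of the spatial Durbin data-generating process."""

    W: SpatialWeightMatrix
    n_years: int = 11
    rho: float = 0.4
    beta: np.ndarray = field(default_factory=lambda: np.array([1.0, -0.5]))
    theta_durbin: np.ndarray | None = None
    fixed_effects: str = "time"  # time | individual | twoway | none
    sigma: float = 1.0
    effect_scale: float = 1.0
    #: scale of persistent unit-specific covariate means (between variation)
    x_between_scale: float = 0.0
    #: strength of unit effects correlated with the unit's covariate level
    #: (what makes random effects inconsistent, as in real provincial data)
    unit_effect_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.theta_durbin is None:
            self.theta_durbin = np.zeros_like(self.beta)
        self.theta_durbin = np.asarray(self.theta_durbin, dtype=float)
        if len(self.theta_durbin) != len(self.beta):
            raise ValueError("beta and theta_durbin must have equal length")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        omega = np.linalg.eigvals(self.W.w).real
        lo = 1.0 / omega.min() if omega.min() < 0 else -1.0
        if not (lo < self.rho < 1.0 / max(omega.max(), 1e-12)):
            raise ValueError(f"rho={self.rho} outside the stable interval")


def generate_sdm_panel(spec: SDMSpec) -> tuple[np.ndarray, np.ndarray]:
    """Simulate y_t = (I - rho W)^{-1}(X b + WX th + effects + eps) per period.

    Returns ``(y, X)`` with shapes (T, n) and (T, n, k); X is iid standard
    normal.
    """
    rng = np.random.default_rng(spec.seed)
    w = spec.W.w
    n = spec.W.n
    T, k = spec.n_years, len(spec.beta)
    A_inv = np.linalg.inv(np.eye(n) - spec.rho * w)
    X = rng.normal(size=(T, n, k))
    if spec.x_between_scale > 0:
        X = X + spec.x_between_scale * rng.normal(size=(1, n, k))
    eps = rng.normal(scale=spec.sigma, size=(T, n)) if spec.sigma > 0 else np.zeros((T, n))

    fe = np.zeros((T, n))
    if spec.fixed_effects in ("time", "twoway"):
        fe += rng.normal(scale=spec.effect_scale, size=(T, 1))
    if spec.fixed_effects in ("individual", "twoway"):
        fe += rng.normal(scale=spec.effect_scale, size=(1, n))
    if spec.unit_effect_corr != 0.0:
        fe = fe + spec.unit_effect_corr * X.mean(axis=(0, 2))[None, :]

    WX = np.einsum("ij,tjk->tik", w, X)
    signal = X @ spec.beta + WX @ spec.theta_durbin + fe + eps
    y = np.einsum("ij,tj->ti", A_inv, signal)
    return y, X


def fixture_table3() -> EfficiencyTable:
    """The packaged published efficiency grid (31 units x 2009-2019).

    Scores are the printed 3-decimal values; the region labels and the
    printed max/min/mean summary columns ride along in ``regions`` and
    ``printed_summary``.
    """
    path = resources.files("healthprod.data").joinpath(
        "china_efficiency_2009_2019.tsv")
    with path.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df = df.set_index("unit")
    years = [c for c in df.columns if c.isdigit()]
    scores = df[years].astype(float)
    scores.columns = [int(c) for c in years]
    table = EfficiencyTable(scores=scores, regions=df["region"].to_dict())
    table.printed_summary = df[["max", "min", "mean"]].astype(float)
    return table
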