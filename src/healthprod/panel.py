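"""Panel containers, long-format I/O, regions, grading and aggregation.

The analysis treats each province-year as a decision-making unit described
by an input/output system (health expenditure, insurance, beds, technicians
as inputs; perinatal survival as the desirable output; medical waste and
mortality as undesirable outputs) plus six regression covariates
(Pgdp, Urb, Med, Mnm, Gov, Pd).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_EVEN

import numpy as np
import pandas as pd

__all__ = [
    "DEAPanel",
    "CovariatePanel",
    "RegionScheme",
    "EfficiencyTable",
    "SchemaError",
    "IntegrityError",
    "load_panel",
    "perinatal_survival",
    "interpolate_missing",
    "assign_regions",
    "aggregate_regional",
    "grade_efficiency",
    "CHINA_REGIONS",
    "COVARIATE_COLUMNS",
    "DEFAULT_SCHEMA",
]

COVARIATE_COLUMNS = ["Pgdp", "Urb", "Med", "Mnm", "Gov", "Pd"]

#: Column roles of the input-output system: four inputs, one desirable
#: output, two undesirable outputs (waste, mortality).
DEFAULT_SCHEMA = {
    "unit": "unit",
    "year": "year",
    "inputs": ["K_e", "K_i", "K_b", "I"],
    "outputs": ["y"],
    "bads": ["B_w", "B_m"],
    "covariates": COVARIATE_COLUMNS,
}


class SchemaError(ValueError):
    """A required column is missing or misdeclared."""


class IntegrityError(ValueError):
    """The table violates a panel invariant (duplicates, gaps, signs)."""


def _as_cube(df: pd.DataFrame, units: list, years: list, cols: list[str]) -> np.ndarray:
    """Stack columns into an array of shape (n_years, n_cols, n_units)."""
    out = np.empty((len(years), len(cols), len(units)))
    for t, yr in enumerate(years):
        sub = df[df["year"] == yr].set_index("unit").loc[units]
        out[t] = sub[cols].to_numpy().T
    return out


@dataclass
class DEAPanel:
    """Balanced units x years panel of the DEA input-output system.

    ``x``, ``y``, ``u`` have shapes (T, m, n), (T, s, n), (T, q, n):
    for each year a matrix of inputs / desirable outputs / undesirable
    outputs over the n units.  All entries must be strictly positive.
    """

    unit_ids: list
    years: list
    x: np.ndarray
    y: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        n, T = len(self.unit_ids), len(self.years)
        for name, arr in (("x", self.x), ("y", self.y), ("u", self.u)):
            if arr.ndim != 3 or arr.shape[0] != T or arr.shape[2] != n:
                raise IntegrityError(f"{name} must have shape (T, *, n) = ({T}, *, {n})")
            if arr.shape[1] < 1:
                raise IntegrityError(f"panel needs at least one {name} row")
            if not np.all(np.isfinite(arr)):
                raise IntegrityError(f"{name} contains missing or non-finite cells")
            if np.any(arr <= 0):
                raise IntegrityError(f"{name} must be strictly positive for DEA")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def cross_section(self, year) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = self.years.index(year)
        return self.x[t], self.y[t], self.u[t]

    def to_frame(self, schema: dict = DEFAULT_SCHEMA) -> pd.DataFrame:
        rows = []
        for t, yr in enumerate(self.years):
            for j, uid in enumerate(self.unit_ids):
                row = {schema["unit"]: uid, schema["year"]: yr}
                row.update({c: self.x[t, i, j] for i, c in enumerate(schema["inputs"])})
                row.update({c: self.y[t, r, j] for r, c in enumerate(schema["outputs"])})
                row.update({c: self.u[t, p, j] for p, c in enumerate(schema["bads"])})
                rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class CovariatePanel:
    """Regression covariates on the same balanced unit-year index."""

    unit_ids: list
    years: list
    data: pd.DataFrame  # MultiIndex (unit, year) x covariate columns

    def __post_init__(self) -> None:
        expected = pd.MultiIndex.from_product(
            [self.unit_ids, self.years], names=["unit", "year"]
        )
        if not self.data.index.equals(expected):
            self.data = self.data.reindex(expected)
        if self.data.isna().any().any():
            raise IntegrityError("covariate panel has missing unit-year cells")

    def matrix(self, columns: list[str] | None = None) -> np.ndarray:
        """Stacked (T*n, k) covariate matrix, year-major then unit order."""
        cols = columns or list(self.data.columns)
        blocks = []
        for yr in self.years:
            sub = self.data.xs(yr, level="year").loc[self.unit_ids]
            blocks.append(sub[cols].to_numpy())
        return np.vstack(blocks)


@dataclass
class RegionScheme:
    """Total partition of the unit labels into named regions."""

    mapping: dict

    def __post_init__(self) -> None:
        self.regions = sorted(set(self.mapping.values()))

    def region_of(self, unit_id) -> str:
        try:
            return self.mapping[unit_id]
        except KeyError:
            raise KeyError(f"unit {unit_id!r} is not covered by the region scheme")

    def members(self, region: str) -> list:
        return [u for u, r in self.mapping.items() if r == region]


#: National Bureau of Statistics four-region economic division of the 31
#: provincial units (Eastern 10, Middle 6, Western 12, Northeastern 3).
CHINA_REGIONS = {
    "BeiJing": "Eastern", "TianJin": "Eastern", "HeBei": "Eastern",
    "GuangDong": "Eastern", "HaiNan": "Eastern", "ShangHai": "Eastern",
    "JiangSu": "Eastern", "ZheJiang": "Eastern", "FuJian": "Eastern",
    "ShanDong": "Eastern",
    "ShanXi": "Middle", "AnHui": "Middle", "JiangXi": "Middle",
    "HeNan": "Middle", "HuBei": "Middle", "HuNan": "Middle",
    "GuangXi": "Western", "ChongQing": "Western", "SiChuan": "Western",
    "GuiZhou": "Western", "YunNan": "Western", "XiZang": "Western",
    "ShaanXi": "Western", "GanSu": "Western", "QingHai": "Western",
    "NingXia": "Western", "XinJiang": "Western", "NeiMengGu": "Western",
    "LiaoNing": "Northeastern", "JiLin": "Northeastern",
    "HeiLongJiang": "Northeastern",
}


@dataclass
class EfficiencyTable:
    """Grid of efficiency scores gamma* over units x years.

    ``scores`` is a DataFrame indexed by unit with one column per year.
    Optional companion grids hold the CRS/VRS decomposition (TE, PTE, SE).
    """

    scores: pd.DataFrame
    te: pd.DataFrame | None = None
    pte: pd.DataFrame | None = None
    se: pd.DataFrame | None = None
    regions: dict | None = None

    @property
    def unit_ids(self) -> list:
        return list(self.scores.index)

    @property
    def years(self) -> list:
        return list(self.scores.columns)

    def row_summary(self) -> pd.DataFrame:
        """Per-unit max / min / mean over the years, unrounded."""
        return pd.DataFrame(
            {
                "max": self.scores.max(axis=1),
                "min": self.scores.min(axis=1),
                "mean": self.scores.mean(axis=1),
            }
        )

    def values_for(self, year) -> np.ndarray:
        return self.scores[year].to_numpy(dtype=float)


def round3(value: float) -> float:
    """Presentation rounding: 3 decimals, half-even, decimal-exact."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.001"), ROUND_HALF_EVEN))


def perinatal_survival(mortality_rate: float) -> float:
    """Convert a perinatal mortality proportion into a survival proportion.

    Survival = 1 - mortality; both live on the unit interval.
    """
    m = np.asarray(mortality_rate, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("mortality rate must lie in [0, 1]")
    out = 1.0 - m
    return float(out) if out.ndim == 0 else out


def interpolate_missing(series) -> np.ndarray:
    """Fill gaps: linear interpolation inside, nearest observed at the edges.

    Observed values are preserved exactly; the operation is idempotent.
    """
    s = pd.Series(np.asarray(series, dtype=float))
    if s.notna().sum() == 0:
        raise ValueError("cannot complete an all-missing series")
    filled = s.interpolate(method="linear", limit_direction="both", limit_area=None)
    # limit_direction="both" also extrapolates edges with nearest value
    return filled.to_numpy()


def assign_regions(unit_ids, scheme_name: str = "china_nbs", mapping: dict | None = None) -> RegionScheme:
    """Map each unit to its region under a named or user-supplied scheme."""
    if mapping is None:
        if scheme_name != "china_nbs":
            raise ValueError(f"unknown region scheme {scheme_name!r}")
        mapping = CHINA_REGIONS
    missing = [u for u in unit_ids if u not in mapping]
    if missing:
        raise KeyError(f"units not covered by region scheme: {missing}")
    return RegionScheme({u: mapping[u] for u in unit_ids})


def aggregate_regional(
    table: EfficiencyTable,
    scheme: RegionScheme,
    stat: str = "mean",
    year=None,
) -> pd.DataFrame:
    """Unweighted regional aggregate of the score grid.

    Returns a region x year DataFrame (single column when ``year`` given).
    Values are unrounded; round at the presentation layer only.
    """
    if stat not in {"mean", "max", "min"}:
        raise ValueError(f"stat must be mean/max/min, got {stat!r}")
    years = [year] if year is not None else table.years
    uncovered = [u for u in table.unit_ids if u not in scheme.mapping]
    if uncovered:
        raise KeyError(f"units not covered by region scheme: {uncovered}")
    out = {}
    for region in scheme.regions:
        members = [u for u in table.unit_ids if scheme.mapping[u] == region]
        if not members:
            raise ValueError(f"region {region!r} has no member units")
        block = table.scores.loc[members, years]
        out[region] = getattr(block, stat)(axis=0)
    return pd.DataFrame(out).T


_BANDS = [(0.8, "low"), (1.0, "medium"), (np.inf, "high")]

#: Default 8-grade refinement: equal 0.1-wide intervals from 0.6 to 1.2
#: with open tails.  Each grade falls inside exactly one band.
DEFAULT_GRADE_EDGES = [0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2]


def grade_efficiency(value: float, grade_edges: list[float] | None = None) -> tuple[str, int]:
    """Classify a score into a coarse band and a fine 1..8 grade.

    Bands use the half-open intervals (0, 0.8] low, (0.8, 1] medium,
    (1, inf) high.  Grades refine the bands with 0.1-wide half-open
    intervals between 0.6 and 1.2 plus open tails.
    """
    v = float(value)
    if v <= 0:
        raise ValueError("efficiency score must be strictly positive")
    if v <= 0.8:
        band = "low"
    elif v <= 1.0:
        band = "medium"
    else:
        band = "high"
    edges = DEFAULT_GRADE_EDGES if grade_edges is None else sorted(grade_edges)
    grade = 1
    for e in edges:
        if v > e:
            grade += 1
    return band, grade


def load_panel(path, schema: dict | None = None) -> tuple[DEAPanel, CovariatePanel]:
    """Read a long-format unit-year CSV into aligned DEA and covariate panels.

    One row per unit-year; ``schema`` maps roles to column names (defaults
    to :data:`DEFAULT_SCHEMA`).  Rows are normalised to unit-then-year order.
    """
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    df = pd.read_csv(path)
    required = (
        [schema["unit"], schema["year"]]
        + schema["inputs"] + schema["outputs"] + schema["bads"] + schema["covariates"]
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"input file lacks required columns: {missing}")
    df = df.rename(columns={schema["unit"]: "unit", schema["year"]: "year"})
    if df.duplicated(["unit", "year"]).any():
        dups = df[df.duplicated(["unit", "year"])][["unit", "year"]].values.tolist()
        raise IntegrityError(f"duplicate unit-year rows: {dups[:5]}")
    df = df.sort_values(["unit", "year"], kind="mergesort").reset_index(drop=True)
    units = list(pd.unique(df["unit"]))
    years = sorted(pd.unique(df["year"]).tolist())
    counts = df.groupby("unit")["year"].count()
    if counts.nunique() != 1 or counts.iloc[0] != len(years):
        raise IntegrityError("panel is unbalanced: units observed in different years")

    dea = DEAPanel(
        unit_ids=units,
        years=years,
        x=_as_cube(df, units, years, schema["inputs"]),
        y=_as_cube(df, units, years, schema["outputs"]),
        u=_as_cube(df, units, years, schema["bads"]),
    )
    cov = df.set_index(["unit", "year"])[schema["covariates"]]
    cov = cov.reindex(pd.MultiIndex.from_product([units, years], names=["unit", "year"]))
    return dea, CovariatePanel(units, years, cov)
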