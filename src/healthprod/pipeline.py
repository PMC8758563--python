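"""End-to-end orchestration: score -> ESDA -> spatial econometrics -> report.

A run is described by a :class:`PipelineConfig` (usually parsed from a YAML
file).  Exactly one efficiency source is configured: a long-format panel
CSV to be scored with the EBM model, a ready-made efficiency table CSV
(or the packaged published grid) that bypasses the DEA stage, or synthetic
specs.  Outputs are tidy CSV tables — per-unit scores with regional
labels, region x year means, per-year global Moran results, local
quadrant/Gi* classifications, econometric diagnostics, SDM coefficients
and effect decomposition — plus a JSON manifest recording seeds and
configuration sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ebm import determine_epsilon_weights, score_panel
from .esda import getis_ord_gstar, local_moran_quadrants, moran_inference
from .panel import (
    CHINA_REGIONS,
    EfficiencyTable,
    aggregate_regional,
    assign_regions,
    grade_efficiency,
    load_panel,
    round3,
)
from .spatial_panel import decompose_effects, select_model
from .synthetic import FrontierSpec, SDMSpec, fixture_table3, generate_frontier_panel, generate_sdm_panel
from .weights import build_contiguity, china_contiguity, row_standardize

__all__ = ["PipelineConfig", "run_pipeline", "write_report", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure with a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage, self.code = stage, code
        super().__init__(f"[{stage}:{code}] {message}")


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    # exactly one efficiency source
    panel_csv: str | None = None
    efficiency_csv: str | None = None    # precomputed scores; "fixture" = packaged grid
    synthetic: dict | None = None        # {"frontier": {...}, "sdm": {...}}

    weights_edges: str | None = None     # edge-list path; None = packaged China W
    region_scheme: str = "china_nbs"
    esda_enabled: bool = True
    econometrics_enabled: bool = True
    n_permutations: int = 999
    alpha: float = 0.05
    effect_draws: int = 1000
    seed: int = 0
    output_dir: str = "healthprod_report"
    overwrite: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError("config", "unknown-field", f"unknown fields {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        sources = [s is not None for s in (self.panel_csv, self.efficiency_csv, self.synthetic)]
        if sum(sources) != 1:
            raise PipelineError(
                "config", "source",
                "exactly one of panel_csv / efficiency_csv / synthetic must be set")
        if self.esda_enabled and self.weights_edges is None and self.synthetic is None \
                and self.efficiency_csv not in (None, "fixture") :
            raise PipelineError(
                "config", "weights",
                "field 'weights_edges' is required when esda_enabled is true "
                "and the units are not the packaged China scheme")


def _efficiency_stage(cfg: PipelineConfig, manifest: dict):
    covariates = None
    dea_panel = None
    if cfg.efficiency_csv is not None:
        if cfg.efficiency_csv == "fixture":
            table = fixture_table3()
            manifest["efficiency_source"] = "packaged published grid"
        else:
            df = pd.read_csv(cfg.efficiency_csv, index_col=0)
            df.columns = [int(c) for c in df.columns]
            table = EfficiencyTable(scores=df)
            manifest["efficiency_source"] = cfg.efficiency_csv
        return table, covariates, dea_panel
    if cfg.panel_csv is not None:
        dea_panel, covariates = load_panel(cfg.panel_csv)
        manifest["efficiency_source"] = cfg.panel_csv
    else:
        spec = FrontierSpec(seed=cfg.seed, **(cfg.synthetic.get("frontier") or {}))
        dea_panel, truth = generate_frontier_panel(spec)
        manifest["efficiency_source"] = "synthetic frontier panel"
        manifest["frontier_spec"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                                     for k, v in vars(spec).items()}
    x0, y0, u0 = dea_panel.x[0], dea_panel.y[0], dea_panel.u[0]
    p0 = determine_epsilon_weights(x0, y0, u0)
    manifest["ebm"] = {
        "epsilon_in_year0": p0.epsilon_in, "epsilon_out_year0": p0.epsilon_out,
        "weights_in_year0": p0.w_in.tolist(),
        "note": "epsilon/weights re-determined per calendar year",
    }
    table = score_panel(dea_panel)
    return table, covariates, dea_panel


def _weights_stage(cfg: PipelineConfig, table: EfficiencyTable, manifest: dict):
    units = table.unit_ids
    if cfg.weights_edges is not None:
        W = row_standardize(build_contiguity(cfg.weights_edges, units))
        manifest["spatial_weights"] = f"user edge list {cfg.weights_edges} (row-standardised)"
        return W
    if set(units) == set(CHINA_REGIONS):
        manifest["spatial_weights"] = "packaged China contiguity (row-standardised)"
        return china_contiguity()
    if cfg.synthetic is not None:
        from .weights import SpatialWeightMatrix
        n = len(units)
        if n == len(CHINA_REGIONS):
            # synthetic units inherit the packaged contiguity topology
            W = SpatialWeightMatrix(units, china_contiguity(standardize=False).w)
            manifest["spatial_weights"] = "packaged contiguity topology (relabelled)"
        else:
            w = np.zeros((n, n))
            for i in range(n - 1):
                w[i, i + 1] = w[i + 1, i] = 1.0
            W = SpatialWeightMatrix(units, w)
            manifest["spatial_weights"] = "path-graph contiguity over synthetic units"
        return row_standardize(W)
    raise PipelineError("esda", "weights",
                        "no weights source for non-China units; set weights_edges")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns {table name: DataFrame}."""
    cfg.validate()
    t_start = time.time()
    manifest: dict = {
        "package": "healthprod", "version": __version__, "seed": cfg.seed,
        "stages": [],
    }
    tables: dict[str, pd.DataFrame | None] = {}

    log.info("stage 1: efficiency scores")
    try:
        table, covariates, dea_panel = _efficiency_stage(cfg, manifest)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("efficiency", "failed", str(exc)) from exc
    manifest["stages"].append("efficiency")

    summary = table.row_summary()
    scores_out = table.scores.copy().round(3)
    for col in ("max", "min", "mean"):
        scores_out[col] = summary[col].map(round3)
    grades = table.scores.map(
        lambda v: grade_efficiency(v)[0] if np.isfinite(v) else "")
    try:
        scheme = assign_regions(table.unit_ids, cfg.region_scheme)
        scores_out["region"] = [scheme.region_of(u) for u in table.unit_ids]
        regional = aggregate_regional(table, scheme, "mean").map(round3)
        tables["regional_means"] = regional
    except KeyError:
        log.info("units not covered by region scheme %r; regional tables skipped",
                 cfg.region_scheme)
        tables["regional_means"] = None
    tables["efficiency_scores"] = scores_out
    tables["efficiency_grades"] = grades

    if cfg.esda_enabled:
        log.info("stage 2: spatial autocorrelation")
        try:
            W = _weights_stage(cfg, table, manifest)
            rows, local_rows = [], []
            for yr in table.years:
                x = table.values_for(yr)
                mask = np.isfinite(x)
                Wy = W
                if not mask.all():
                    # drop units with missing scores (infeasible DEA cells)
                    log.info("%d unit(s) without a score in %s excluded from ESDA",
                             (~mask).sum(), yr)
                    from .weights import SpatialWeightMatrix
                    sub = [lab for lab, ok in zip(W.labels, mask) if ok]
                    Wy = row_standardize(SpatialWeightMatrix(
                        sub, W.w[np.ix_(mask, mask)]))
                    x = x[mask]
                r = moran_inference(x, Wy, method="permutation",
                                    n_perm=cfg.n_permutations, seed=cfg.seed)
                rows.append({"year": yr, "I": r.I, "expected": r.expected,
                             "z": r.z, "p": r.p})
                quad = local_moran_quadrants(x, Wy)
                gi = getis_ord_gstar(x, Wy)
                for lab, qd, g in zip(quad.labels, quad.quadrant, gi):
                    local_rows.append({"unit": lab, "year": yr,
                                       "quadrant": qd, "gi_star": g})
            tables["global_moran"] = pd.DataFrame(rows).set_index("year")
            tables["local_clusters"] = pd.DataFrame(local_rows)
            manifest["stages"].append("esda")
            manifest["esda"] = {"n_permutations": cfg.n_permutations, "seed": cfg.seed}
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("esda", "failed", str(exc)) from exc
    else:
        tables["global_moran"] = tables["local_clusters"] = None
        W = None

    if cfg.econometrics_enabled:
        log.info("stage 3: spatial panel econometrics")
        try:
            y, X, names, W_econ = _econ_inputs(cfg, table, covariates, W, manifest)
        except PipelineError as exc:
            if exc.code != "no-covariates":
                raise
            y = None
        if y is None:
            log.info("no covariates available; econometric stage skipped")
            for nm in ("ht_tests", "lm_tests", "lr_wald", "sdm_coefficients", "effects"):
                tables[nm] = None
        else:
            try:
                fit, report = select_model(y, X, W_econ, alpha=cfg.alpha,
                                           covariate_names=names, seed=cfg.seed)
                tables["ht_tests"] = report.ht
                lm = pd.DataFrame(report.lm, index=["statistic", "p"]).T
                if report.hausman is not None:
                    lm.loc["hausman"] = [report.hausman[0], report.hausman[2]]
                tables["lm_tests"] = lm
                tables["lr_wald"] = report.lr_wald
                tables["sdm_coefficients"] = fit.summary_frame()
                if fit.rho is not None:
                    eff = decompose_effects(fit, W_econ, n_draws=cfg.effect_draws,
                                            seed=cfg.seed, names=names)
                    tables["effects"] = eff.to_frame()
                else:
                    tables["effects"] = None
                manifest["stages"].append("econometrics")
                manifest["econometrics"] = {
                    "chosen_model": fit.model, "effects": fit.effects,
                    "alpha": cfg.alpha, "effect_draws": cfg.effect_draws,
                    "r2_by_effects": report.r2_by_effects,
                }
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError("econometrics", "failed", str(exc)) from exc

    log.info("pipeline finished in %.2f s", time.time() - t_start)
    tables["_manifest"] = manifest
    return tables


def _econ_inputs(cfg, table, covariates, W, manifest):
    """Assemble (y, X, names, W) for the econometric stage."""
    if cfg.synthetic is not None and "sdm" in (cfg.synthetic or {}):
        sdm_kwargs = dict(cfg.synthetic["sdm"])
        W_econ = W if W is not None else china_contiguity()
        for key in ("beta", "theta_durbin"):
            if key in sdm_kwargs:
                sdm_kwargs[key] = np.asarray(sdm_kwargs[key], dtype=float)
        spec = SDMSpec(W=W_econ, seed=cfg.seed, **sdm_kwargs)
        y, X = generate_sdm_panel(spec)
        manifest["sdm_spec"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                                for k, v in vars(spec).items() if k != "W"}
        names = [f"x{i}" for i in range(X.shape[2])]
        return y, X, names, W_econ
    if covariates is None:
        raise PipelineError("econometrics", "no-covariates",
                            "no covariate source configured")
    years, units = table.years, table.unit_ids
    T, n = len(years), len(units)
    y = np.vstack([table.values_for(yr) for yr in years])
    names = list(covariates.data.columns)
    X = covariates.matrix(names).reshape(T, n, len(names))
    return y, X, names, W


def write_report(tables: dict, outdir, overwrite: bool = False) -> list[str]:
    """Write one CSV per table plus manifest.json; refuse a dirty directory.

    ``None`` tables are omitted and listed in the manifest.  Returns the
    file names written.
    """
    out = Path(outdir)
    manifest = dict(tables.get("_manifest") or {})
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise PipelineError("report", "exists",
                            f"output dir {out} is not empty (use overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    written, omitted = [], []
    for name, df in tables.items():
        if name.startswith("_"):
            continue
        if df is None or (hasattr(df, "empty") and df.empty):
            omitted.append(name)
            continue
        path = out / f"{name}.csv"
        df.to_csv(path)
        written.append(path.name)
    manifest["tables"] = sorted(written)
    manifest["omitted_tables"] = sorted(omitted)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return written + ["manifest.json"]
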