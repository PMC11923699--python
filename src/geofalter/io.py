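"""Readers, writers, configuration and the staged pipeline.

Formats are deliberately plain: cluster tables as UTF-8 CSV with a header
('.' decimal), rasters as ESRI ASCII grids, polygons as GeoJSON, fitted
parameters as YAML, and a JSON manifest recording seeds, checksums and
per-stage outputs so a run can be reproduced exactly.  All writes go
through a write-temp-then-rename helper so an interrupted run never
leaves a truncated file behind.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import shapely.geometry
import yaml

from .covariates import build_design
from .data import ClusterData
from .grids import Raster, read_ascii_grid, write_ascii_grid
from .model import FitResult, GeoModelParams, fit_mle, scan_lags
from .predict import (
    PredictiveSurface,
    aggregate_polygons,
    counts_surface,
    krige_latent,
    prevalence_surface,
)
from .synthetic import SimulationConfig, simulate_survey

logger = logging.getLogger("geofalter")

__all__ = [
    "read_cluster_table",
    "write_cluster_table",
    "read_polygons",
    "write_fit_yaml",
    "read_fit_yaml",
    "PipelineConfig",
    "run_pipeline",
    "atomic_write_text",
]

REQUIRED_COLUMNS = ("cluster_id", "x_km", "y_km", "birth_month")


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` via a temp file + rename (atomic on POSIX)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_cluster_table(path, outcome_cols=None) -> ClusterData:
    """Load and validate a per-individual cluster CSV.

    Requires cluster_id, x_km, y_km, birth_month plus at least one
    z-score column; raises a descriptive error for missing columns,
    non-numeric coordinates or an empty file.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty cluster table")
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    for col in ("x_km", "y_km"):
        if not np.issubdtype(pd.to_numeric(df[col], errors="coerce").dtype, np.number):
            raise ValueError(f"{path}: column {col!r} is not numeric")
        if pd.to_numeric(df[col], errors="coerce").isna().any():
            raise ValueError(f"{path}: non-numeric values in column {col!r}")
    data = ClusterData.from_frame(df, outcome_cols=outcome_cols)
    logger.info(
        "read %s: %d individuals in %d clusters",
        path, data.n_individuals, data.n_clusters,
    )
    return data


def write_cluster_table(path, data: ClusterData) -> None:
    atomic_write_text(path, data.to_frame().to_csv(index=False))


def read_polygons(path) -> dict[str, shapely.Geometry]:
    """Read a GeoJSON FeatureCollection into {feature id/name: geometry}."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")
    out: dict[str, shapely.Geometry] = {}
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        name = str(props.get("name", props.get("id", feat.get("id", i))))
        out[name] = shapely.geometry.shape(feat["geometry"])
    if not out:
        raise ValueError(f"{path}: no features")
    return out


def _params_to_dict(p: GeoModelParams) -> dict:
    return {
        "alpha": float(p.alpha),
        "beta": [float(b) for b in p.beta],
        "sigma2": float(p.sigma2),
        "phi": None if not p.spatial else float(p.phi),
        "omega2": float(p.omega2),
    }


def params_from_dict(d: dict) -> GeoModelParams:
    return GeoModelParams(
        alpha=float(d["alpha"]),
        beta=np.asarray(d.get("beta", []), dtype=float),
        sigma2=float(d["sigma2"]),
        phi=float("nan") if d.get("phi") is None else float(d["phi"]),
        omega2=float(d["omega2"]),
    )


def write_fit_yaml(path, fit: FitResult) -> None:
    doc = {
        "params": _params_to_dict(fit.params),
        "log_likelihood": float(fit.log_likelihood),
        "aic": float(fit.aic),
        "n_individuals": int(fit.n_individuals),
        "n_clusters": int(fit.n_clusters),
        "converged": bool(fit.converged),
        "spatial": bool(fit.spatial),
        "phi_identifiable": bool(fit.phi_identifiable),
        "n_free_params": int(fit.n_free_params),
        "messages": list(fit.messages),
        "conf_int": {
            str(k): {
                "estimate": float(r["estimate"]),
                "ci_lower": float(r["ci_lower"]),
                "ci_upper": float(r["ci_upper"]),
            }
            for k, r in fit.conf_int.iterrows()
        },
    }
    atomic_write_text(path, yaml.safe_dump(doc, sort_keys=False))


def read_fit_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def fit_result_from_yaml(doc: dict) -> FitResult:
    """Rebuild a FitResult (without the full CI table's p-values) from a
    serialized fit, sufficient for the prediction pipeline."""
    conf = pd.DataFrame(doc.get("conf_int", {})).T
    conf.index.name = "parameter"
    return FitResult(
        params=params_from_dict(doc["params"]),
        log_likelihood=float(doc["log_likelihood"]),
        aic=float(doc["aic"]),
        conf_int=conf,
        n_individuals=int(doc["n_individuals"]),
        n_clusters=int(doc["n_clusters"]),
        converged=bool(doc["converged"]),
        n_free_params=int(doc["n_free_params"]),
        spatial=bool(doc.get("spatial", True)),
        phi_identifiable=bool(doc.get("phi_identifiable", True)),
        messages=list(doc.get("messages", [])),
    )


@dataclass
class PipelineConfig:
    """End-to-end synthetic pipeline settings.

    The pipeline runs simulate -> extract -> scan-lags -> fit -> predict ->
    aggregate on a synthetic survey; seeds for every random stage are
    explicit so a rerun reproduces the outputs bit-for-bit (CSV/YAML) or
    to float tolerance (grids).
    """

    out_dir: str
    outcome: str = "haz"
    threshold: float = -2.0
    n_sims: int = 1000
    seed: int = 0
    scan_covariate: str = "spei"
    scan_lags_range: tuple[int, int] = (1, 12)
    n_districts: int = 4
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.threshold >= 0:
            raise ValueError("undernutrition threshold must be negative")
        if self.outcome not in ("haz", "waz", "whz"):
            raise ValueError("outcome must be one of haz, waz, whz")


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _grid_polygons(config: PipelineConfig, geom) -> dict[str, shapely.Geometry]:
    """Split the domain into vertical district strips (synthetic admin map)."""
    k = max(config.n_districts, 1)
    edges = np.linspace(geom.x0, geom.x1, k + 1)
    return {
        f"district_{i}": shapely.box(edges[i], geom.ybottom, edges[i + 1], geom.ytop)
        for i in range(k)
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write a reproducibility manifest.

    Returns the manifest dict (also written to ``manifest.json``); any
    stage failure raises with the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "outcome": config.outcome,
        "stages": [],
        "outputs": {},
    }
    stage_ctx: dict = {}

    def run_stage(name, fn):
        t0 = time.time()
        logger.info("stage %s: start", name)
        try:
            outputs = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        elapsed = time.time() - t0
        manifest["stages"].append(
            {"name": name, "outputs": sorted(outputs), "seconds": round(elapsed, 3)}
        )
        for rel in outputs:
            manifest["outputs"][rel] = _checksum(out / rel)
        logger.info("stage %s: done in %.2fs", name, elapsed)

    def stage_simulate():
        sim_cfg = SimulationConfig(
            **{**config.simulation.__dict__, "seed": config.seed}
        )
        survey = simulate_survey(sim_cfg, outcome=config.outcome)
        stage_ctx["survey"] = survey
        write_cluster_table(out / "clusters.csv", survey.data)
        write_ascii_grid(out / "population.asc", survey.population)
        truth = {
            "true_params": _params_to_dict(survey.true_params),
            "true_lags": dict(sim_cfg.true_lags),
        }
        atomic_write_text(out / "truth.yaml", yaml.safe_dump(truth))
        return ["clusters.csv", "population.asc", "truth.yaml"]

    def stage_extract():
        survey = stage_ctx["survey"]
        xy = survey.data.individual_xy
        design = build_design(
            survey.stack, xy[:, 0], xy[:, 1], survey.data.birth_month,
            lags=dict(survey.config.true_lags),
        )
        stage_ctx["design"] = design
        atomic_write_text(out / "design.csv", design.values.to_csv(index=False))
        return ["design.csv"]

    def stage_scan_lags():
        survey = stage_ctx["survey"]
        design = stage_ctx["design"]
        xy = survey.data.individual_xy
        name = config.scan_covariate
        series = survey.stack.extract_monthly(name, xy[:, 0], xy[:, 1])
        lo, hi = config.scan_lags_range
        from .covariates import build_lagged_column

        cols = {
            d: build_lagged_column(series, survey.data.birth_month, d)
            for d in range(lo, hi + 1)
        }
        scan = scan_lags(
            survey.data.z(config.outcome), design, survey.data.cluster_xy,
            survey.data.cluster_index, name, cols,
        )
        stage_ctx["scan"] = scan
        atomic_write_text(out / "lag_scan.csv", scan.table.to_csv(index=False))
        return ["lag_scan.csv"]

    def stage_fit():
        survey = stage_ctx["survey"]
        scan = stage_ctx["scan"]
        design = stage_ctx["design"]
        xy = survey.data.individual_xy
        name = config.scan_covariate
        series = survey.stack.extract_monthly(name, xy[:, 0], xy[:, 1])
        from .covariates import build_lagged_column

        col = build_lagged_column(
            series, survey.data.birth_month, scan.selected_lag
        )
        design = design.with_column(name, col, lag=scan.selected_lag)
        stage_ctx["design"] = design
        fit = fit_mle(
            survey.data.z(config.outcome), design.values,
            survey.data.cluster_xy, survey.data.cluster_index,
            column_names=design.columns,
        )
        stage_ctx["fit"] = fit
        write_fit_yaml(out / "fit.yaml", fit)
        return ["fit.yaml"]

    def stage_predict():
        survey = stage_ctx["survey"]
        fit = stage_ctx["fit"]
        design = stage_ctx["design"]
        geom = survey.stack.geometry
        gx, gy = geom.center_mesh()
        # grid design: constant layers at cell values, monthly layers at
        # their temporal mean, standardized with the training record
        raw = {}
        for name in design.columns:
            if name in survey.stack.constant_layers:
                raw[name] = survey.stack.extract_constant(name, gx, gy)
            else:
                mean_r = survey.stack.monthly_mean_raster(name)
                from .grids import extract_at_points

                raw[name] = extract_at_points(mean_r, gx, gy)[0]
        grid_design = design.record.apply(pd.DataFrame(raw))[design.columns]
        latent = krige_latent(
            fit, survey.data.z(config.outcome), design.values,
            survey.data.cluster_xy, survey.data.cluster_index,
            np.column_stack([gx, gy]),
        )
        prev = prevalence_surface(
            fit, latent, grid_design, threshold=config.threshold,
            method="closed_form", n_sims=config.n_sims, seed=config.seed,
        )
        cases = counts_surface(prev, survey.population)
        p = fit.params
        mean = p.alpha + grid_design.to_numpy() @ p.beta + latent.mean
        sd = np.sqrt(latent.variance + p.omega2)
        surface = PredictiveSurface(
            geometry=geom, mean=mean, sd=sd, prevalence=prev, cases=cases,
            n_sims=config.n_sims,
        )
        stage_ctx["prevalence"] = surface.prevalence
        stage_ctx["cases"] = surface.cases
        for fname, which in [
            ("prevalence.asc", "prevalence"), ("cases.asc", "cases"),
            ("pred_mean.asc", "mean"), ("pred_sd.asc", "sd"),
        ]:
            write_ascii_grid(out / fname, surface.raster(which))
        return ["prevalence.asc", "cases.asc", "pred_mean.asc", "pred_sd.asc"]

    def stage_aggregate():
        survey = stage_ctx["survey"]
        polys = _grid_polygons(config, survey.stack.geometry)
        summary = aggregate_polygons(
            stage_ctx["prevalence"], survey.population, polys
        )
        atomic_write_text(out / "districts.csv", summary.table.to_csv(index=False))
        gj = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {
                        "name": row["district"],
                        "population": row["population"],
                        "cases": row["cases"],
                        "prevalence": row["prevalence"],
                    },
                    "geometry": json.loads(
                        shapely.to_geojson(polys[row["district"]])
                    ),
                }
                for _, row in summary.table.iterrows()
            ],
        }
        atomic_write_text(out / "districts.geojson", json.dumps(gj, indent=1))
        return ["districts.csv", "districts.geojson"]

    run_stage("simulate", stage_simulate)
    run_stage("extract", stage_extract)
    run_stage("scan_lags", stage_scan_lags)
    run_stage("fit", stage_fit)
    run_stage("predict", stage_predict)
    run_stage("aggregate", stage_aggregate)

    atomic_write_text(out / "manifest.json", json.dumps(manifest, indent=1))
    return manifest
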