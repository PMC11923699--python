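"""Kriging prediction, prevalence surfaces, case counts and aggregation.

Given a fitted model, the latent spatial process S is predicted at grid
locations by conditional-Gaussian (kriging) formulas with the MLEs plugged
in.  The z-score of an unobserved child at grid cell x is then
Y_new = alpha + beta'D(x) + S(x) + U_new, and prevalence of growth
faltering at x is P(Y_new < threshold) with threshold -2 (the WHO cutoff
defining stunting / underweight / wasting on HAZ / WAZ / WHZ).

Two prevalence paths are provided and must agree: the closed form
Phi((t - m(x)) / sqrt(v(x) + omega^2)) using the kriging mean and
variance, and averaging Phi((t - alpha - beta'D - S_s)/omega) over joint
conditional simulations of S.  The closed form is exact under the model;
the simulation path exists because district-level nonlinear functionals of
jointly dependent cells need joint draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist
from scipy.stats import norm
import shapely

from .grids import GridGeometry, Raster
from .model import FitResult, JITTER, _cluster_corr, _factor_with_jitter

__all__ = [
    "KrigingResult",
    "PredictiveSurface",
    "DistrictSummary",
    "krige_latent",
    "prevalence_surface",
    "counts_surface",
    "aggregate_polygons",
]


@dataclass
class KrigingResult:
    """Conditional (plug-in posterior) distribution of S at grid points."""

    mean: np.ndarray
    variance: np.ndarray
    covariance: np.ndarray | None = None  # joint, for conditional simulation

    def draw(self, n_sims: int, rng: np.random.Generator) -> np.ndarray:
        """(n_sims, n_points) joint conditional draws of S."""
        if self.covariance is None:
            raise ValueError("joint covariance was not requested at kriging time")
        cov = self.covariance + JITTER * np.eye(len(self.mean))
        L = np.linalg.cholesky(cov)
        eps = rng.standard_normal((n_sims, len(self.mean)))
        return self.mean + eps @ L.T


def krige_latent(
    fit: FitResult,
    y: np.ndarray,
    X: np.ndarray | pd.DataFrame,
    cluster_xy: np.ndarray,
    cluster_index: np.ndarray,
    grid_xy: np.ndarray,
    return_cov: bool = False,
) -> KrigingResult:
    """Kriging mean and variance of the latent field S at grid points.

    Works on cluster-level sufficient statistics: with residual cluster
    means rbar (sizes m_i), the conditional distribution of S at x is
    Gaussian with mean c(x)' V^-1 rbar and variance
    sigma^2 - c(x)' V^-1 c(x), where V = sigma^2 K + omega^2 diag(1/m)
    and c(x)_i = sigma^2 exp(-||x - x_i||/phi).  This equals the dense
    individual-level conditional-Gaussian formula exactly.

    For a non-spatial fit (phi not identifiable), S carries no information
    to new locations: mean 0, variance sigma^2.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    grid_xy = np.asarray(grid_xy, dtype=float)
    p = fit.params
    g = len(grid_xy)

    if not p.spatial:
        var = np.full(g, p.sigma2)
        cov = p.sigma2 * np.eye(g) if return_cov else None
        return KrigingResult(np.zeros(g), var, cov)

    cluster_xy = np.asarray(cluster_xy, dtype=float)
    cluster_index = np.asarray(cluster_index, dtype=int)
    c = len(cluster_xy)
    m = np.bincount(cluster_index, minlength=c).astype(float)
    resid = y - p.alpha - (X @ p.beta if X.size else 0.0)
    rbar = np.bincount(cluster_index, weights=resid, minlength=c) / m

    K = _cluster_corr(cluster_xy, p.phi, True)
    V = p.sigma2 * K + np.diag(p.omega2 / m)
    cho = _factor_with_jitter(V, p.sigma2 + p.omega2, p.phi)

    C = p.sigma2 * np.exp(-cdist(grid_xy, cluster_xy) / p.phi)  # (g, c)
    ViC = cho_solve(cho, C.T)  # (c, g)
    mean = C @ cho_solve(cho, rbar)
    if return_cov:
        Kgg = p.sigma2 * np.exp(-cdist(grid_xy, grid_xy) / p.phi)
        cov = Kgg - C @ ViC
        var = np.clip(np.diag(cov).copy(), 0.0, None)
        return KrigingResult(mean, var, cov)
    var = np.clip(p.sigma2 - np.einsum("gc,cg->g", C, ViC), 0.0, None)
    return KrigingResult(mean, var, None)


def prevalence_surface(
    fit: FitResult,
    latent: KrigingResult,
    grid_design: np.ndarray | pd.DataFrame,
    threshold: float = -2.0,
    method: str = "closed_form",
    n_sims: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Per-point probability that a new individual's z-score falls below
    ``threshold``.

    ``grid_design`` must already be standardized with the *training*
    means/SDs.  Cells with non-finite design values come back NaN (masked)
    rather than raising.
    """
    if isinstance(grid_design, pd.DataFrame):
        grid_design = grid_design.to_numpy(dtype=float)
    Xg = np.asarray(grid_design, dtype=float)
    if Xg.ndim == 1:
        Xg = Xg[:, None]
    p = fit.params
    n_pts = len(latent.mean)
    if Xg.shape[1]:
        if Xg.shape[0] != n_pts:
            raise ValueError("grid design rows do not match latent points")
        lin = p.alpha + Xg @ p.beta
        mask = np.all(np.isfinite(Xg), axis=1)
    else:
        lin = np.full(n_pts, p.alpha)
        mask = np.ones(n_pts, dtype=bool)

    if method == "closed_form":
        m = lin + latent.mean
        sd = np.sqrt(latent.variance + p.omega2)
        prev = norm.cdf((threshold - m) / sd)
    elif method == "simulation":
        if n_sims < 500:
            raise ValueError("simulation path requires n_sims >= 500")
        rng = np.random.default_rng(seed)
        draws = latent.draw(n_sims, rng)  # (n_sims, g)
        omega = np.sqrt(p.omega2)
        prev = norm.cdf((threshold - lin[None, :] - draws) / omega).mean(axis=0)
    else:
        raise ValueError(f"unknown method {method!r}")
    prev = np.asarray(prev, dtype=float)
    prev[~mask] = np.nan
    return prev


@dataclass
class PredictiveSurface:
    """Gridded predictive summaries sharing one geometry."""

    geometry: GridGeometry
    mean: np.ndarray  # predictive mean of alpha + beta'D + S
    sd: np.ndarray  # predictive SD of a new individual's z-score
    prevalence: np.ndarray
    cases: np.ndarray | None = None
    n_sims: int = 0

    def __post_init__(self) -> None:
        shape = self.geometry.shape
        for name in ("mean", "sd", "prevalence"):
            arr = np.asarray(getattr(self, name), dtype=float).reshape(shape)
            setattr(self, name, arr)
        if self.cases is not None:
            self.cases = np.asarray(self.cases, dtype=float).reshape(shape)
        finite = self.prevalence[np.isfinite(self.prevalence)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("prevalence must lie in [0, 1]")

    def raster(self, which: str) -> Raster:
        return Raster(self.geometry, getattr(self, which))


def counts_surface(prevalence: np.ndarray, population: Raster) -> np.ndarray:
    """Expected cases per cell: prevalence x under-5 population, cellwise.

    Masked (NaN) prevalence cells propagate to NaN counts.
    """
    prev = np.asarray(prevalence, dtype=float)
    if prev.size != population.values.size:
        raise ValueError("prevalence and population grids do not match")
    prev = prev.reshape(population.geometry.shape)
    return prev * population.values


@dataclass
class DistrictSummary:
    """Population-weighted prevalence and absolute burden per polygon."""

    table: pd.DataFrame  # district, population, cases, prevalence, n_cells
    n_unassigned_cells: int
    unassigned_cases: float
    flags: dict[str, str] = field(default_factory=dict)


def aggregate_polygons(
    prevalence: np.ndarray,
    population: Raster,
    polygons: dict[str, shapely.Geometry],
) -> DistrictSummary:
    """Aggregate a prevalence surface to administrative polygons.

    Cells are assigned to the polygon containing their center; per
    polygon, cases = sum(prevalence x population) over member cells and
    prevalence = cases / population.  Cells whose center lies in no
    polygon are counted and reported, never silently dropped.  Zero-
    population polygons get NaN prevalence and a flag.
    """
    geom = population.geometry
    prev = np.asarray(prevalence, dtype=float).reshape(geom.shape)
    cases = counts_surface(prev, population)
    xs, ys = geom.center_mesh()
    pop = population.values.ravel()
    case_flat = cases.ravel()
    assigned = np.zeros(len(xs), dtype=bool)

    rows = []
    flags: dict[str, str] = {}
    for name, poly in polygons.items():
        inside = shapely.contains_xy(poly, xs, ys) & ~assigned
        assigned |= inside
        pop_d = float(np.nansum(pop[inside]))
        cases_d = float(np.nansum(case_flat[inside]))
        if pop_d > 0:
            prev_d = cases_d / pop_d
        else:
            prev_d = np.nan
            flags[name] = "zero population: prevalence undefined"
        rows.append(
            {
                "district": name,
                "population": pop_d,
                "cases": cases_d,
                "prevalence": prev_d,
                "n_cells": int(inside.sum()),
            }
        )
    n_out = int((~assigned).sum())
    out_cases = float(np.nansum(case_flat[~assigned]))
    return DistrictSummary(
        table=pd.DataFrame(rows),
        n_unassigned_cells=n_out,
        unassigned_cases=out_cases,
        flags=flags,
    )
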