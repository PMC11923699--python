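"""Synthetic survey generator: the study conditions in miniature.

Emulates a DHS-like cluster survey of child anthropometry together with
the gridded environment it sits in: spatially clustered survey locations,
temporally constant covariate rasters (aridity-, slope-like), monthly
covariate series with sinusoidal 12-month seasonality plus spatially
correlated, temporally independent anomalies (rainfall-, SPEI-, EVI-like),
an under-5 population raster, and z-score outcomes drawn from the exact
linear geostatistical model

    Y_ij = alpha + beta' D(x_i) + S(x_i) + U_ij

with S an exponential-correlation Gaussian process shared by all
individuals of a cluster and U iid nugget noise.  Default true parameters
sit near the fitted height-for-age values (alpha = -1.23, sigma2 = 0.15,
phi = 18.28 km, omega2 = 2.02, one SPEI-like covariate with beta = 0.06),
so every downstream stage can be tested against known truth without the
restricted-access survey data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .covariates import CovariateStack, DesignMatrix, build_design
from .data import ClusterData
from .grids import GridGeometry, Raster
from .model import GeoModelParams, JITTER

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "gen_cluster_locations",
    "gen_covariate_fields",
    "simulate_zscores",
    "gen_population_raster",
    "simulate_survey",
    "SyntheticSurvey",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One synthetic covariate field.

    temporal: "constant" (single raster) or "monthly" (series of rasters).
    spatial_range_km: exponential-correlation scale of the field.
    marginal_sd: SD of the (anomaly) field.
    seasonal_amplitude: amplitude of the 12-month sinusoidal mean cycle
        (monthly covariates only; an SPEI-like standardized index has a
        small amplitude, a rainfall-like series a large one).
    seasonal_phase: month offset of the cycle peak.
    """

    name: str
    temporal: str = "constant"
    spatial_range_km: float = 50.0
    marginal_sd: float = 1.0
    seasonal_amplitude: float = 0.0
    seasonal_phase: float = 0.0
    mean: float = 0.0

    def __post_init__(self) -> None:
        if self.temporal not in ("constant", "monthly"):
            raise ValueError("temporal must be 'constant' or 'monthly'")
        if self.marginal_sd < 0:
            raise ValueError("marginal_sd must be nonnegative")


def _default_covariates() -> tuple[CovariateSpec, ...]:
    return (
        CovariateSpec("aridity", "constant", spatial_range_km=120.0, marginal_sd=1.0),
        CovariateSpec(
            "spei",
            "monthly",
            spatial_range_km=80.0,
            marginal_sd=1.0,
            seasonal_amplitude=0.3,
        ),
    )


def _default_params() -> GeoModelParams:
    # HAZ-like truth: one constant covariate (null) + one SPEI-like effect
    return GeoModelParams(
        alpha=-1.23, beta=np.array([0.0, 0.06]), sigma2=0.15, phi=18.28, omega2=2.02
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one synthetic survey.

    domain_extent: (xmin, xmax, ymin, ymax) in projected km.
    individuals_per_cluster: inclusive (low, high) of the uniform count of
        measured children per cluster.
    n_months: length of every monthly covariate series; must exceed the
        longest candidate lag (12) so a lagged value exists for every
        feasible birth month.
    grid_cell_km: raster resolution of the synthetic geography.
    """

    domain_extent: tuple[float, float, float, float] = (0.0, 500.0, 0.0, 500.0)
    n_clusters: int = 300
    individuals_per_cluster: tuple[int, int] = (5, 15)
    true_params: GeoModelParams = field(default_factory=_default_params)
    covariate_specs: tuple[CovariateSpec, ...] = field(
        default_factory=_default_covariates
    )
    true_lags: dict[str, int] | None = None
    n_months: int = 36
    grid_cell_km: float = 10.0
    population_total: float = 7.2e6
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, xmax, ymin, ymax = self.domain_extent
        if (xmax - xmin) <= 0 or (ymax - ymin) <= 0:
            raise ValueError("domain extent must have positive area")
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if self.n_months < 13:
            raise ValueError("n_months must be >= 13 so every lag 1..12 exists")
        lo, hi = self.individuals_per_cluster
        if lo < 1 or hi < lo:
            raise ValueError("individuals_per_cluster must be a valid range")
        if self.true_lags is None:
            # default: every monthly covariate acts at lag 3
            object.__setattr__(
                self,
                "true_lags",
                {s.name: 3 for s in self.covariate_specs if s.temporal == "monthly"},
            )
        for name in self.true_lags:
            if name not in {s.name for s in self.covariate_specs}:
                raise ValueError(f"true lag given for unknown covariate {name!r}")

    def geometry(self) -> GridGeometry:
        xmin, xmax, ymin, ymax = self.domain_extent
        nx = max(int(np.ceil((xmax - xmin) / self.grid_cell_km)), 1)
        ny = max(int(np.ceil((ymax - ymin) / self.grid_cell_km)), 1)
        return GridGeometry(
            x0=xmin, ytop=ymax, dx=self.grid_cell_km, dy=self.grid_cell_km,
            nx=nx, ny=ny,
        )


def gen_cluster_locations(config: SimulationConfig) -> pd.DataFrame:
    """Draw cluster locations uniformly over the domain.

    Survey clusters in the field are chosen with probability proportional
    to population; without a census frame, uniform is the neutral stand-in.
    Returns a table (cluster_id, x_km, y_km); no two clusters coincide.
    """
    rng = np.random.default_rng(config.seed)
    xmin, xmax, ymin, ymax = config.domain_extent
    n = config.n_clusters
    x = rng.uniform(xmin, xmax, size=n)
    y = rng.uniform(ymin, ymax, size=n)
    # continuous uniforms never tie in practice; guard anyway
    while len(np.unique(np.column_stack([x, y]), axis=0)) < n:  # pragma: no cover
        x = rng.uniform(xmin, xmax, size=n)
        y = rng.uniform(ymin, ymax, size=n)
    return pd.DataFrame({"cluster_id": np.arange(n), "x_km": x, "y_km": y})


def _gp_field_factor(geometry: GridGeometry, range_km: float) -> np.ndarray:
    """Cholesky factor of an exponential-covariance field on cell centers."""
    xx, yy = geometry.center_mesh()
    pts = np.column_stack([xx, yy])
    from scipy.spatial.distance import cdist

    if range_km <= 0:
        # white-noise limit: independent cells
        return np.eye(len(pts))
    K = np.exp(-cdist(pts, pts) / range_km)
    K[np.diag_indices_from(K)] += JITTER
    return np.linalg.cholesky(K)


def gen_covariate_fields(config: SimulationConfig) -> CovariateStack:
    """Simulate every covariate raster / monthly series of the config.

    Constant covariates are one spatially correlated Gaussian field each.
    Monthly covariates are a sinusoidal 12-month seasonal mean plus an
    independent spatially correlated anomaly field per month; the
    month-to-month independence of anomalies is what makes lagged copies
    of the series distinguishable downstream.
    """
    if not config.covariate_specs:
        raise ValueError("covariate_specs must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    geom = config.geometry()
    shape = geom.shape
    constant: dict[str, Raster] = {}
    monthly: dict[str, list[Raster]] = {}
    for spec in config.covariate_specs:
        L = _gp_field_factor(geom, spec.spatial_range_km)

        def draw_field() -> np.ndarray:
            z = rng.standard_normal(L.shape[0])
            return (spec.marginal_sd * (L @ z)).reshape(shape)

        if spec.temporal == "constant":
            constant[spec.name] = Raster(geom, spec.mean + draw_field())
        else:
            series = []
            for t in range(config.n_months):
                seasonal = spec.mean + spec.seasonal_amplitude * np.sin(
                    2.0 * np.pi * (t - spec.seasonal_phase) / 12.0
                )
                series.append(Raster(geom, seasonal + draw_field()))
            monthly[spec.name] = series
    return CovariateStack(geom, constant, monthly)


def simulate_zscores(
    locations: np.ndarray,
    cluster_index: np.ndarray,
    design: np.ndarray | pd.DataFrame,
    true_params: GeoModelParams,
    seed: int,
) -> np.ndarray:
    """Draw z-scores from the generative model at known parameters.

    One S value is drawn per cluster from the multivariate normal with
    covariance sigma2 * exp(-u/phi); all individuals of a cluster share
    it; nugget noise U is iid N(0, omega2).  The returned vector is
    exactly alpha + beta'D + S + U.
    """
    locations = np.asarray(locations, dtype=float)
    cluster_index = np.asarray(cluster_index, dtype=int)
    if isinstance(design, pd.DataFrame):
        design = design.to_numpy(dtype=float)
    design = np.asarray(design, dtype=float)
    if design.ndim == 1:
        design = design[:, None]
    if design.shape[0] != len(cluster_index):
        raise ValueError("design rows must align with individuals")
    if design.shape[1] != len(true_params.beta):
        raise ValueError("design columns must match beta length")
    rng = np.random.default_rng(seed)
    c = len(locations)
    if true_params.sigma2 > 0:
        from scipy.spatial.distance import cdist

        if true_params.spatial:
            K = np.exp(-cdist(locations, locations) / true_params.phi)
        else:
            K = np.eye(c)
        cov = true_params.sigma2 * K
        cov[np.diag_indices_from(cov)] += JITTER
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"spatial covariance not positive definite after jitter "
                f"(phi={true_params.phi!r}, n={c}): {exc}"
            ) from exc
        S = L @ rng.standard_normal(c)
    else:
        S = np.zeros(c)
    n = len(cluster_index)
    U = (
        np.sqrt(true_params.omega2) * rng.standard_normal(n)
        if true_params.omega2 > 0
        else np.zeros(n)
    )
    lin = true_params.alpha + (design @ true_params.beta if design.size else 0.0)
    return lin + S[cluster_index] + U


def gen_population_raster(
    config: SimulationConfig, clustered: bool = True
) -> Raster:
    """Under-5 population counts per cell, summing to the configured total.

    ``clustered=True`` concentrates people in a smooth log-Gaussian
    density (towns and countryside); ``False`` spreads the total evenly.
    Counts are nonnegative integers (largest-remainder rounding preserves
    the total exactly).
    """
    geom = config.geometry()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    ncell = geom.nx * geom.ny
    if clustered:
        L = _gp_field_factor(geom, 0.25 * min(
            config.domain_extent[1] - config.domain_extent[0],
            config.domain_extent[3] - config.domain_extent[2],
        ))
        dens = np.exp(L @ rng.standard_normal(ncell))
        weights = dens / dens.sum()
    else:
        weights = np.full(ncell, 1.0 / ncell)
    target = float(config.population_total)
    raw = weights * target
    base = np.floor(raw)
    remainder = int(round(target - base.sum()))
    frac_order = np.argsort(-(raw - base))
    base[frac_order[:remainder]] += 1
    return Raster(geom, base.reshape(geom.shape))


def parameter_recovery(
    config: SimulationConfig,
    n_replicates: int = 50,
    outcome: str = "haz",
    base_seed: int = 0,
) -> pd.DataFrame:
    """Fit the model to its own simulations and tabulate recovery.

    Each replicate redraws the whole survey (locations, fields, outcomes)
    at a fresh seed, refits by maximum likelihood, and records estimates
    and whether the 95% CI covered the truth.  Variance parameters are
    compared on the log scale, matching how their CIs are formed.
    Returns one row per (replicate, parameter) with columns
    estimate / truth / covered.
    """
    from .model import fit_mle

    rows = []
    for rep in range(n_replicates):
        cfg = replace(config, seed=base_seed + rep)
        sv = simulate_survey(cfg, outcome=outcome)
        d = sv.data
        fit = fit_mle(
            d.z(outcome), sv.design.values, d.cluster_xy, d.cluster_index,
            check_identifiability=False,
        )
        tp = cfg.true_params
        truths = {"alpha": tp.alpha}
        for name, b in zip(sv.design.columns, tp.beta):
            truths[name] = b
        truths.update(
            {
                "log_sigma2": np.log(tp.sigma2),
                "log_phi": np.log(tp.phi),
                "log_omega2": np.log(tp.omega2),
            }
        )
        ci = fit.conf_int
        for par, truth in truths.items():
            if par.startswith("log_"):
                row = ci.loc[par[4:]]
                est = np.log(row["estimate"])
                lo, hi = np.log(row["ci_lower"]), np.log(row["ci_upper"])
            else:
                row = ci.loc[par]
                est, lo, hi = row["estimate"], row["ci_lower"], row["ci_upper"]
            rows.append(
                {
                    "replicate": rep,
                    "parameter": par,
                    "estimate": est,
                    "truth": truth,
                    "covered": bool(lo <= truth <= hi),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SyntheticSurvey:
    """Everything one synthetic study run produces, plus its truth."""

    config: SimulationConfig
    data: ClusterData
    design: DesignMatrix
    stack: CovariateStack
    population: Raster
    true_params: GeoModelParams

    @property
    def outcome(self) -> str:
        return self.data.outcomes.columns[0]


def simulate_survey(config: SimulationConfig, outcome: str = "haz") -> SyntheticSurvey:
    """End-to-end draw of a synthetic survey under the configured truth.

    Generates locations, covariate fields and population, assigns each
    child a birth month (uniform over months >= 12 so every lag 1..12
    exists), builds the standardized design at the configured true lags,
    and simulates z-scores from the exact model.
    """
    loc_df = gen_cluster_locations(config)
    stack = gen_covariate_fields(config)
    population = gen_population_raster(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    lo, hi = config.individuals_per_cluster
    sizes = rng.integers(lo, hi + 1, size=config.n_clusters)
    cluster_index = np.repeat(np.arange(config.n_clusters), sizes)
    n = len(cluster_index)
    birth_month = rng.integers(12, config.n_months, size=n)
    xy = loc_df[["x_km", "y_km"]].to_numpy()
    x_ind = xy[cluster_index, 0]
    y_ind = xy[cluster_index, 1]
    design = build_design(
        stack, x_ind, y_ind, birth_month, lags=dict(config.true_lags)
    )
    z = simulate_zscores(
        xy,
        cluster_index,
        design.values,
        config.true_params,
        seed=int(np.random.SeedSequence([config.seed, 4]).generate_state(1)[0] % (2**31)),
    )
    data = ClusterData(
        cluster_ids=loc_df["cluster_id"].to_numpy(),
        cluster_xy=xy,
        cluster_index=cluster_index,
        birth_month=birth_month,
        outcomes=pd.DataFrame({outcome: z}),
    )
    return SyntheticSurvey(
        config=config,
        data=data,
        design=design,
        stack=stack,
        population=population,
        true_params=config.true_params,
    )
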