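"""Covariate extraction, lagging, standardization and timescale selection.

Covariates come in two temporal kinds: *constant* rasters (aridity, slope,
travel time, nighttime lights, long-run mean temperature) and *monthly*
series (rainfall-, SPEI-, EVI-like).  Time-varying covariates enter the
model lagged relative to each child's birth month: lag d means the value in
calendar month (birth_month - d), so lag 0 is the birth month itself and
candidate lags run from birth back 12 months.

All covariates are standardized (zero mean, unit SD over the fitted
individuals) before entering the design matrix, so a regression coefficient
reads as the change in mean z-score per 1 SD of the covariate.  The
training means/SDs are kept so prediction grids are transformed with the
*same* record, never re-standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridGeometry, Raster, extract_at_points

__all__ = [
    "CovariateStack",
    "StandardizationRecord",
    "DesignMatrix",
    "build_lagged_column",
    "standardize",
    "destandardize",
    "select_spei_timescale",
    "pairwise_correlation_report",
]


@dataclass
class CovariateStack:
    """Named gridded covariates on one shared grid geometry.

    ``monthly_layers`` maps a name to an ordered list of rasters, one per
    calendar month index 0..n_months-1 with no gaps.
    """

    geometry: GridGeometry
    constant_layers: dict[str, Raster] = field(default_factory=dict)
    monthly_layers: dict[str, list[Raster]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, r in self.constant_layers.items():
            if r.geometry != self.geometry:
                raise ValueError(f"constant layer {name!r} is on a different grid")
        lengths = {len(v) for v in self.monthly_layers.values()}
        if len(lengths) > 1:
            raise ValueError("monthly layers must share a common series length")
        for name, series in self.monthly_layers.items():
            for r in series:
                if r.geometry != self.geometry:
                    raise ValueError(f"monthly layer {name!r} is on a different grid")

    @property
    def names(self) -> list[str]:
        return list(self.constant_layers) + list(self.monthly_layers)

    @property
    def n_months(self) -> int:
        if not self.monthly_layers:
            return 0
        return len(next(iter(self.monthly_layers.values())))

    def extract_constant(self, name: str, x, y) -> np.ndarray:
        vals, _ = extract_at_points(self.constant_layers[name], x, y)
        return vals

    def extract_monthly(self, name: str, x, y) -> np.ndarray:
        """(n_months, n_points) matrix of the series at the given points."""
        series = self.monthly_layers[name]
        return np.vstack([extract_at_points(r, x, y)[0] for r in series])

    def monthly_mean_raster(self, name: str) -> Raster:
        """Temporal mean of a monthly series, as a raster."""
        series = self.monthly_layers[name]
        return Raster(self.geometry, np.mean([r.values for r in series], axis=0))


def build_lagged_column(
    monthly_values: np.ndarray, birth_month: np.ndarray, lag: int
) -> np.ndarray:
    """Per-individual covariate value ``lag`` months before birth.

    Parameters
    ----------
    monthly_values : (n_months, n_individuals) series already extracted at
        each individual's location.
    birth_month : (n,) calendar-month index of each birth (0-based).
    lag : months before birth; lag 0 is the birth month.
    """
    monthly_values = np.asarray(monthly_values, dtype=float)
    birth_month = np.asarray(birth_month, dtype=int)
    if lag < 0:
        raise ValueError("lag must be nonnegative")
    target = birth_month - lag
    if target.min() < 0:
        earliest = int(lag)  # earliest feasible birth month index for this lag
        raise ValueError(
            f"lag {lag} precedes the series start for some births; "
            f"earliest feasible birth month index is {earliest}"
        )
    if target.max() >= monthly_values.shape[0]:
        raise ValueError("birth month beyond the end of the covariate series")
    return monthly_values[target, np.arange(len(birth_month))]


@dataclass(frozen=True)
class StandardizationRecord:
    """Per-column training mean and SD, reused verbatim on new data."""

    mean: pd.Series
    sd: pd.Series

    def apply(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col in self.mean.index:
            out[col] = (df[col] - self.mean[col]) / self.sd[col]
        return out

    def invert(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col in self.mean.index:
            out[col] = df[col] * self.sd[col] + self.mean[col]
        return out


def standardize(
    df: pd.DataFrame, record: StandardizationRecord | None = None
) -> tuple[pd.DataFrame, StandardizationRecord]:
    """Center and scale every column to mean 0, SD 1 (population SD).

    Passing an existing record applies the *training* transform instead of
    refitting — the grid-prediction path must use this.
    """
    if record is None:
        mean = df.mean()
        sd = df.std(ddof=0)
        zero = sd.index[sd <= 0]
        if len(zero):
            raise ValueError(f"zero-variance column(s): {list(zero)}")
        record = StandardizationRecord(mean=mean, sd=sd)
    return record.apply(df), record


def destandardize(df: pd.DataFrame, record: StandardizationRecord) -> pd.DataFrame:
    return record.invert(df)


@dataclass
class DesignMatrix:
    """Standardized per-individual covariates plus provenance.

    ``lags`` records the lag assignment of each time-varying column;
    constant columns are absent from it.
    """

    values: pd.DataFrame
    record: StandardizationRecord
    lags: dict[str, int] = field(default_factory=dict)

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def with_column(self, name: str, column: np.ndarray, lag: int | None = None):
        """Return a copy with one raw column replaced (re-standardized alone)."""
        col = pd.DataFrame({name: np.asarray(column, dtype=float)})
        std_col, rec = standardize(col)
        values = self.values.copy()
        values[name] = std_col[name].to_numpy()
        mean = self.record.mean.copy()
        sd = self.record.sd.copy()
        mean[name] = rec.mean[name]
        sd[name] = rec.sd[name]
        lags = dict(self.lags)
        if lag is not None:
            lags[name] = lag
        return DesignMatrix(values, StandardizationRecord(mean, sd), lags)


def build_design(
    stack: CovariateStack,
    x: np.ndarray,
    y: np.ndarray,
    birth_month: np.ndarray,
    lags: dict[str, int],
    constant_names: list[str] | None = None,
) -> DesignMatrix:
    """Extract, lag and standardize covariates into a design matrix.

    ``lags`` names the monthly covariates to include and their lag in
    months; ``constant_names`` defaults to every constant layer.
    Rows with any missing extracted value are kept but flagged NaN; the
    fitting layer drops and reports them.
    """
    cols: dict[str, np.ndarray] = {}
    if constant_names is None:
        constant_names = list(stack.constant_layers)
    for name in constant_names:
        cols[name] = stack.extract_constant(name, x, y)
    for name, lag in lags.items():
        series = stack.extract_monthly(name, x, y)
        cols[name] = build_lagged_column(series, birth_month, lag)
    raw = pd.DataFrame(cols)
    std, rec = standardize(raw)
    return DesignMatrix(std, rec, dict(lags))


def select_spei_timescale(
    spei_by_timescale: dict[int, np.ndarray], vegetation: np.ndarray
) -> tuple[int, pd.DataFrame]:
    """Choose the drought-index accumulation timescale tracking vegetation.

    The SPEI is multiscalar: an n-month timescale accumulates the climatic
    water balance over the previous n months.  The timescale whose series
    has the highest Pearson correlation with a vegetation index (pooled
    over all location-month pairs) is selected; ties go to the shorter
    timescale.

    Returns ``(selected_timescale, table)`` where the table has one row per
    candidate with its correlation and the number of pairs used.
    """
    if len(spei_by_timescale) < 2:
        raise ValueError("need at least two candidate timescales")
    veg = np.asarray(vegetation, dtype=float).ravel()
    rows = []
    for ts in sorted(spei_by_timescale):
        s = np.asarray(spei_by_timescale[ts], dtype=float).ravel()
        if s.shape != veg.shape:
            raise ValueError(
                f"timescale {ts}: series shape {s.shape} does not match vegetation"
            )
        ok = np.isfinite(s) & np.isfinite(veg)
        if ok.sum() < 3:
            raise ValueError(f"timescale {ts}: fewer than 3 overlapping pairs")
        r = float(np.corrcoef(s[ok], veg[ok])[0, 1])
        rows.append({"timescale": ts, "pearson_r": r, "n_pairs": int(ok.sum())})
    table = pd.DataFrame(rows)
    best_r = table["pearson_r"].max()
    # ties (to float precision) break toward the shorter timescale
    winners = table.loc[table["pearson_r"] >= best_r - 1e-12, "timescale"]
    return int(winners.min()), table


def pairwise_correlation_report(series: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pearson correlation of every covariate pair over pooled finite values.

    Used to flag redundant covariates (e.g. two vegetation indices that
    track each other almost perfectly); the configuration, not the code,
    decides which of a redundant pair to keep.
    """
    names = list(series)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va = np.asarray(series[a], dtype=float).ravel()
            vb = np.asarray(series[b], dtype=float).ravel()
            ok = np.isfinite(va) & np.isfinite(vb)
            r = float(np.corrcoef(va[ok], vb[ok])[0, 1]) if ok.sum() >= 3 else np.nan
            rows.append({"a": a, "b": b, "pearson_r": r, "n_pairs": int(ok.sum())})
    return pd.DataFrame(rows)
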