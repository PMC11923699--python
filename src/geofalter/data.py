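"""Observation containers for cluster-survey anthropometry.

The observation unit is the survey cluster: a GPS-located sampling point at
which several children were measured.  Continuous anthropometric z-scores
(HAZ / WAZ / WHZ relative to the WHO 2006 growth standards) are stored per
individual; coordinates are stored once per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ClusterData"]


@dataclass
class ClusterData:
    """Per-cluster coordinates plus per-individual outcomes.

    Parameters
    ----------
    cluster_ids : (c,) array of cluster labels (unique).
    cluster_xy : (c, 2) array of projected coordinates in km.
    cluster_index : (n,) int array mapping each individual to a cluster row.
    birth_month : (n,) int array, calendar-month index into a monthly
        covariate series (0-based).
    outcomes : DataFrame with one column per z-score outcome (e.g. ``haz``),
        n rows aligned with ``cluster_index``.
    """

    cluster_ids: np.ndarray
    cluster_xy: np.ndarray
    cluster_index: np.ndarray
    birth_month: np.ndarray
    outcomes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.cluster_ids = np.asarray(self.cluster_ids)
        self.cluster_xy = np.asarray(self.cluster_xy, dtype=float)
        self.cluster_index = np.asarray(self.cluster_index, dtype=int)
        self.birth_month = np.asarray(self.birth_month, dtype=int)
        c = len(self.cluster_ids)
        if self.cluster_xy.shape != (c, 2):
            raise ValueError("cluster_xy must be (n_clusters, 2)")
        if len(np.unique(self.cluster_ids)) != c:
            raise ValueError("cluster ids must be unique")
        n = len(self.cluster_index)
        if len(self.birth_month) != n or len(self.outcomes) != n:
            raise ValueError("per-individual arrays must share length")
        if self.cluster_index.min(initial=0) < 0 or (
            n and self.cluster_index.max() >= c
        ):
            raise ValueError("cluster_index out of range")

    @property
    def n_individuals(self) -> int:
        return len(self.cluster_index)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    @property
    def individual_xy(self) -> np.ndarray:
        """(n, 2) coordinates: individuals inherit their cluster location."""
        return self.cluster_xy[self.cluster_index]

    def z(self, outcome: str) -> np.ndarray:
        return self.outcomes[outcome].to_numpy(dtype=float)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_index, minlength=self.n_clusters)

    def to_frame(self) -> pd.DataFrame:
        """Long per-individual table (cluster_id, x_km, y_km, birth_month, z...)."""
        df = pd.DataFrame(
            {
                "cluster_id": self.cluster_ids[self.cluster_index],
                "x_km": self.cluster_xy[self.cluster_index, 0],
                "y_km": self.cluster_xy[self.cluster_index, 1],
                "birth_month": self.birth_month,
            }
        )
        for col in self.outcomes.columns:
            df[col] = self.outcomes[col].to_numpy()
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, outcome_cols=None) -> "ClusterData":
        required = {"cluster_id", "x_km", "y_km", "birth_month"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        if outcome_cols is None:
            outcome_cols = [c for c in df.columns if c not in required]
        if not outcome_cols:
            raise ValueError("no outcome (z-score) columns found")
        ids, index = np.unique(df["cluster_id"].to_numpy(), return_inverse=True)
        xy = np.empty((len(ids), 2))
        xy[index, 0] = df["x_km"].to_numpy(dtype=float)
        xy[index, 1] = df["y_km"].to_numpy(dtype=float)
        # verify one location per cluster
        for k in range(len(ids)):
            rows = np.flatnonzero(index == k)
            if not (
                np.allclose(df["x_km"].to_numpy()[rows], xy[k, 0])
                and np.allclose(df["y_km"].to_numpy()[rows], xy[k, 1])
            ):
                raise ValueError(f"cluster {ids[k]!r} has inconsistent coordinates")
        return cls(
            cluster_ids=ids,
            cluster_xy=xy,
            cluster_index=index,
            birth_month=df["birth_month"].to_numpy(dtype=int),
            outcomes=df[list(outcome_cols)].reset_index(drop=True),
        )
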