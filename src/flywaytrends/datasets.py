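"""In-memory containers for counts, comparative data and tree sets.

Counts live in a long-format :class:`pandas.DataFrame` with one row per
non-missing replicate count (``site_id, node_id, year, month, count``).
Missing replicates are simply absent rows; the likelihood skips them.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

COUNT_COLUMNS = ["site_id", "node_id", "year", "month", "count"]

#: Covariates of the comparative analysis, in canonical column order.
COVARIATE_COLUMNS = [
    "yellow_sea_reliance",
    "migration_distance",
    "breeding_range_size",
    "generation_time",
    "body_size",
]


class DataValidationError(ValueError):
    """Raised when an input table violates the dataset schema."""


@dataclass
class CountDataset:
    """Replicated count data: sites nested in nodes, counted in years/months.

    Parameters
    ----------
    df
        Long-format table with columns ``site_id, node_id, year, month, count``.
        One row per realised replicate count; a missing replicate is an
        absent row. Counts are nonnegative integers.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise DataValidationError(f"count table missing columns: {missing}")
        df = df[COUNT_COLUMNS].copy()
        df = df.dropna(subset=["count"])
        df["count"] = df["count"].astype(int)
        df["year"] = df["year"].astype(int)
        if (df["count"] < 0).any():
            rows = df.index[df["count"] < 0].tolist()
            raise DataValidationError(f"negative counts at rows {rows}")
        dup = df.duplicated(subset=["site_id", "year", "month"])
        if dup.any():
            rows = df.index[dup].tolist()
            raise DataValidationError(
                f"duplicate (site, year, month) rows at {rows}"
            )
        node_per_site = df.groupby("site_id")["node_id"].nunique()
        bad = node_per_site[node_per_site > 1]
        if len(bad):
            raise DataValidationError(
                f"sites mapped to multiple nodes: {bad.index.tolist()}"
            )
        self.df = df.reset_index(drop=True)

    # -- indexing ---------------------------------------------------------
    @property
    def sites(self) -> list:
        return sorted(self.df["site_id"].unique().tolist())

    @property
    def nodes(self) -> list:
        return sorted(self.df["node_id"].unique().tolist())

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.df["year"].unique())

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def node_of_site(self) -> dict:
        return dict(self.df.groupby("site_id")["node_id"].first())

    def year_center(self) -> float:
        """Mean year t*; the trend covariate is (year - t*)."""
        return float(self.years.mean())

    def to_arrays(self):
        """Pack counts into padded (site-year, replicate) arrays for fitting.

        Returns a dict with: counts ``C`` (S, J) int, mask ``M`` (S, J) bool,
        ``sy_site`` (S,) site index, ``sy_year`` (S,) year index, ``site_node``
        (R,) node index, ``x_year`` (K,) centred year values, plus label lists.
        """
        sites = self.sites
        nodes = self.nodes
        years = self.years
        site_ix = {s: i for i, s in enumerate(sites)}
        node_ix = {n: i for i, n in enumerate(nodes)}
        year_ix = {int(y): i for i, y in enumerate(years)}
        nos = self.node_of_site()
        site_node = np.array([node_ix[nos[s]] for s in sites], dtype=int)

        grouped = self.df.groupby(["site_id", "year"])["count"]
        keys = sorted(grouped.groups.keys(), key=lambda k: (site_ix[k[0]], k[1]))
        J = int(grouped.size().max())
        S = len(keys)
        C = np.zeros((S, J), dtype=int)
        M = np.zeros((S, J), dtype=bool)
        sy_site = np.zeros(S, dtype=int)
        sy_year = np.zeros(S, dtype=int)
        for s, key in enumerate(keys):
            vals = grouped.get_group(key).to_numpy()
            C[s, : len(vals)] = vals
            M[s, : len(vals)] = True
            sy_site[s] = site_ix[key[0]]
            sy_year[s] = year_ix[int(key[1])]
        x_year = years.astype(float) - self.year_center()
        return {
            "C": C,
            "M": M,
            "sy_site": sy_site,
            "sy_year": sy_year,
            "site_node": site_node,
            "x_year": x_year,
            "sites": sites,
            "nodes": nodes,
            "years": years,
        }

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountDataset):
            return NotImplemented
        a = self.df.sort_values(COUNT_COLUMNS).reset_index(drop=True)
        b = other.df.sort_values(COUNT_COLUMNS).reset_index(drop=True)
        return a.equals(b)


@dataclass
class ComparativeDataset:
    """Taxon-level trend estimates with candidate covariates.

    ``df`` columns: ``taxon, trend, trend_lo, trend_hi`` plus one column per
    covariate. Yellow Sea reliance is a proportion in [0, 1] on the raw scale.
    """

    df: pd.DataFrame
    covariates: Sequence[str] = field(default_factory=lambda: list(COVARIATE_COLUMNS))

    def __post_init__(self) -> None:
        self.covariates = [c for c in self.covariates if c in self.df.columns]
        required = ["taxon", "trend"] + list(self.covariates)
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise DataValidationError(f"comparative table missing columns: {missing}")
        if self.df[list(self.covariates)].isna().any().any():
            raise DataValidationError("missing covariate values")
        if "yellow_sea_reliance" in self.df.columns:
            r = self.df["yellow_sea_reliance"]
            if ((r < 0) | (r > 1)).any():
                raise DataValidationError("yellow_sea_reliance outside [0, 1]")
        self.df = self.df.reset_index(drop=True)

    @property
    def taxa(self) -> list:
        return self.df["taxon"].tolist()

    @property
    def n_taxa(self) -> int:
        return len(self.df)

    def response(self) -> np.ndarray:
        return self.df["trend"].to_numpy(dtype=float)

    def covariate_matrix(self) -> np.ndarray:
        return self.df[list(self.covariates)].to_numpy(dtype=float)

    def standardized(self):
        """Z-score response and covariates; returns (y, X, metadata)."""
        y = self.response()
        X = self.covariate_matrix()
        meta = {
            "y_mean": float(y.mean()),
            "y_sd": float(y.std(ddof=0)),
            "x_mean": X.mean(axis=0),
            "x_sd": X.std(axis=0, ddof=0),
        }
        if meta["y_sd"] == 0 or np.any(meta["x_sd"] == 0):
            raise DataValidationError("zero-variance response or covariate")
        ys = (y - meta["y_mean"]) / meta["y_sd"]
        Xs = (X - meta["x_mean"]) / meta["x_sd"]
        return ys, Xs, meta


@dataclass
class TreeSet:
    """A set of ultrametric trees sharing one tip-label set."""

    trees: dendropy.TreeList
    ultrametric_tol: float = 1e-6

    def __post_init__(self) -> None:
        if len(self.trees) == 0:
            raise DataValidationError("empty tree set")
        labels0 = self.tip_labels()
        for i, t in enumerate(self.trees):
            labels = sorted(lf.taxon.label for lf in t.leaf_node_iter())
            if labels != labels0:
                raise DataValidationError(
                    f"tree {i} tip set {labels} differs from first tree {labels0}"
                )

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_tips(self) -> int:
        return len(self.trees[0].leaf_nodes())

    def tip_labels(self) -> list:
        return sorted(lf.taxon.label for lf in self.trees[0].leaf_node_iter())

    def root_to_tip_heights(self, index: int = 0) -> np.ndarray:
        tree = self.trees[index]
        return np.array(
            [lf.distance_from_root() for lf in tree.leaf_node_iter()], dtype=float
        )

    def is_ultrametric(self, index: int = 0, tol: float | None = None) -> bool:
        h = self.root_to_tip_heights(index)
        tol = self.ultrametric_tol if tol is None else tol
        return bool(h.max() - h.min() <= tol * max(1.0, h.max()))

    def as_newick(self) -> str:
        return "\n".join(
            t.as_string(schema="newick", suppress_rooting=True).strip()
            for t in self.trees
        )


def load_table1() -> pd.DataFrame:
    """Packaged fixture: flyway trend estimates, 95% CRI and Yellow Sea
    reliance for the ten EAAF shorebird taxa, transcribed from the published
    report table. ``endemic`` flags EAAF-endemic taxa."""
    ref = importlib.resources.files("flywaytrends").joinpath("data/table1.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)
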