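"""Report-level quantities derived from posterior trend slopes.

Converts per-year log-scale slopes into percent-per-year trends, classifies
taxa as credibly declining/increasing (95% CRI excluding zero), averages
trends within Yellow Sea reliance groups, and computes the standardized
reliance–trend relationship.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import load_table1


def classify_trend(lo: float, hi: float) -> str:
    """Credible-trend rule: decline iff the 95% CRI lies entirely below 0,
    increase iff entirely above; an endpoint exactly at 0 is 'not credible'."""
    if lo > hi:
        raise ValueError(f"interval ({lo}, {hi}) has lo > hi")
    if hi < 0:
        return "credible decline"
    if lo > 0:
        return "credible increase"
    return "not credible"


def percent_per_year(beta: float, transform: str = "linear") -> float:
    """Per-year percent change from a log-scale slope.

    ``linear`` (default) returns 100*beta, the small-slope approximation the
    report tables use; ``exp`` returns 100*(exp(beta)-1).
    """
    if transform == "linear":
        return 100.0 * beta
    if transform == "exp":
        return 100.0 * (np.expm1(beta))
    raise ValueError(f"unknown transform {transform!r}")


@dataclass
class TrendTable:
    """Per-taxon flyway trends with reliance and credibility flags.

    Columns: taxon, reliance, trend (posterior mean log-scale slope),
    lo, hi (95% CRI), endemic; adds classification and percent columns.
    """

    df: pd.DataFrame
    transform: str = "linear"

    def __post_init__(self) -> None:
        req = {"taxon", "reliance", "trend", "lo", "hi"}
        missing = req - set(self.df.columns)
        if missing:
            raise ValueError(f"trend table missing columns: {sorted(missing)}")
        df = self.df.copy()
        bad = df[(df["lo"] > df["trend"]) | (df["trend"] > df["hi"])]
        if len(bad):
            raise ValueError(
                f"trend outside its own CRI for taxa {bad['taxon'].tolist()}"
            )
        df["classification"] = [
            classify_trend(lo, hi) for lo, hi in zip(df["lo"], df["hi"])
        ]
        df["credible_decline"] = df["classification"] == "credible decline"
        df["percent_per_year"] = [
            percent_per_year(b, self.transform) for b in df["trend"]
        ]
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_table1(cls, **kw) -> "TrendTable":
        return cls(df=load_table1(), **kw)


def count_credible_declines(table: TrendTable) -> int:
    """Number of taxa whose 95% CRI lies entirely below zero."""
    return int(table.df["credible_decline"].sum())


def group_mean_trend(table: TrendTable, reliance_threshold: float,
                     side: str, transform: str = "linear") -> float:
    """Mean percent-per-year trend of a Yellow Sea reliance group.

    ``side='low'`` selects reliance <= threshold, ``side='high'`` selects
    reliance >= threshold; the threshold itself belongs to the group on
    either side. Returns the arithmetic mean of the per-taxon percent
    trends.
    """
    df = table.df
    if side == "low":
        grp = df[df["reliance"] <= reliance_threshold]
    elif side == "high":
        grp = df[df["reliance"] >= reliance_threshold]
    else:
        raise ValueError(f"side must be 'low' or 'high', got {side!r}")
    if len(grp) == 0:
        raise ValueError(
            f"no taxa with reliance {side} of {reliance_threshold}"
        )
    return float(np.mean([percent_per_year(b, transform) for b in grp["trend"]]))


def reliance_trend_slope(table: TrendTable, exclude: tuple = (),
                         level: float = 0.95):
    """Standardized slope of trend on Yellow Sea reliance (tree-free).

    Both variables are z-scored across taxa, so the slope equals the Pearson
    correlation; the interval is the normal-theory confidence interval of
    the standardized regression slope. For the phylogenetic version use
    :func:`flywaytrends.phylo.fit_bvs_regression`.

    Returns (slope, lo, hi).
    """
    df = table.df
    if exclude:
        df = df[~df["taxon"].isin(exclude)]
    n = len(df)
    if n < 3:
        raise ValueError(f"need >= 3 taxa, got {n}")
    x = df["reliance"].to_numpy(dtype=float)
    y = df["trend"].to_numpy(dtype=float)
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        raise ValueError("zero-variance reliance or trend")
    xs = (x - x.mean()) / x.std(ddof=0)
    ys = (y - y.mean()) / y.std(ddof=0)
    slope = float(xs @ ys / (xs @ xs))
    resid = ys - slope * xs
    se = float(np.sqrt((resid @ resid) / (n - 2) / (xs @ xs)))
    tcrit = stats.t.ppf(0.5 + level / 2, n - 2)
    return slope, slope - tcrit * se, slope + tcrit * se


def trend_report(table: TrendTable, low_threshold: float = 0.40,
                 high_threshold: float = 0.50,
                 exclude_from_slope: tuple = ("baueri bar-tailed godwit",)
                 ) -> dict:
    """Headline summary: decline count, group means and reliance slope."""
    slope, lo, hi = reliance_trend_slope(table, exclude=exclude_from_slope)
    return {
        "n_taxa": len(table.df),
        "n_credible_declines": count_credible_declines(table),
        "low_group_mean_pct": group_mean_trend(table, low_threshold, "low"),
        "high_group_mean_pct": group_mean_trend(table, high_threshold, "high"),
        "reliance_slope": slope,
        "reliance_slope_lo": lo,
        "reliance_slope_hi": hi,
    }
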