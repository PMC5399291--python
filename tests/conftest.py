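import warnings

import dendropy
import numpy as np
import pandas as pd
import pytest

from flywaytrends.datasets import ComparativeDataset, TreeSet
from flywaytrends.synthetic import CountSimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_counts():
    """Two nodes x two sites x eight years; modest abundance."""
    cfg = CountSimConfig(
        n_nodes=2, n_sites_per_node=2, n_years=8,
        node_intercepts=(3.5, 3.2), node_trends=(-0.05, 0.0),
        replicates_per_year=(2, 3), seed=42,
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def default_counts():
    """The default study-like design (4 nodes x 4 sites x 20 years)."""
    cfg = CountSimConfig(node_trends=(-0.04,) * 4, seed=7)
    return simulate_counts(cfg)


@pytest.fixture
def three_taxon_tree():
    return dendropy.Tree.get(
        data="((A:1,B:1):1,C:2);", schema="newick", rooting="default-rooted"
    )


def star_tree_set(taxa, height=1.0):
    nwk = "(" + ",".join(f"'{t}':{height}" for t in taxa) + ");"
    trees = dendropy.TreeList.get(
        data=nwk, schema="newick", rooting="default-rooted"
    )
    return TreeSet(trees=trees)


@pytest.fixture
def table1_reliance_data():
    """Nine-taxon comparative table (reliance only) from the packaged
    report-table fixture, excluding the baueri bar-tailed godwit."""
    from flywaytrends.datasets import load_table1

    t1 = load_table1()
    t1 = t1[t1.taxon != "baueri bar-tailed godwit"].reset_index(drop=True)
    df = pd.DataFrame({
        "taxon": t1.taxon, "trend": t1.trend,
        "trend_lo": t1.lo, "trend_hi": t1.hi,
        "yellow_sea_reliance": t1.reliance,
    })
    return ComparativeDataset(df=df, covariates=["yellow_sea_reliance"])


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="non-converged MCMC")
        warnings.filterwarnings("ignore", message=".*weakly identified.*")
        yield


def fit_quietly(fn, *args, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*args, **kw)
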