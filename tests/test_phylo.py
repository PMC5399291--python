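"""Brownian VCV construction and the selection regression."""

import dendropy
import numpy as np
import pandas as pd
import pytest

from flywaytrends.datasets import ComparativeDataset
from flywaytrends.phylo import (
    BVSConfig,
    build_vcv_array,
    classify_indicator,
    fit_bvs_regression,
    scale_and_invert,
    two_stage_selection,
    vcv_from_tree,
)
from flywaytrends.synthetic import (
    ComparativeSimConfig,
    simulate_tree_set,
    simulate_trend_data,
)
from tests.conftest import fit_quietly, star_tree_set


# -- VCV construction -------------------------------------------------------

def test_three_taxon_hand_example(three_taxon_tree):
    V = vcv_from_tree(three_taxon_tree, taxon_order=["A", "B", "C"])
    assert np.allclose(V, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])


def test_star_tree_vcv_is_diagonal():
    ts = star_tree_set(["a", "b", "c", "d"], height=3.0)
    V = vcv_from_tree(ts.trees[0])
    assert np.allclose(V, 3.0 * np.eye(4))


def test_vcv_against_mrca_depth_oracle():
    """Independent route: cov(a,b) = (depth_a + depth_b - patristic(a,b))/2."""
    for seed in range(12):
        ts = simulate_tree_set(
            ComparativeSimConfig(n_taxa=7, n_trees=1, seed=seed)
        )
        tree = ts.trees[0]
        order = ts.tip_labels()
        V = vcv_from_tree(tree, taxon_order=order)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        depth = {
            lf.taxon.label: lf.distance_from_root()
            for lf in tree.leaf_node_iter()
        }
        for i, a in enumerate(order):
            assert V[i, i] == pytest.approx(depth[a], abs=1e-8)
            for j, b in enumerate(order):
                if i >= j:
                    continue
                want = 0.5 * (depth[a] + depth[b]
                              - pdm.patristic_distance(taxa[a], taxa[b]))
                assert V[i, j] == pytest.approx(want, abs=1e-8)


def test_vcv_rejects_bad_trees():
    t = dendropy.Tree.get(data="((A:1,B:1):1,C:2);", schema="newick",
                          rooting="default-rooted")
    t.is_rooted = False
    with pytest.raises(ValueError, match="rooted"):
        vcv_from_tree(t)
    t2 = dendropy.Tree.get(data="((A:1,B:-1):1,C:2);", schema="newick",
                           rooting="default-rooted")
    with pytest.raises(ValueError, match="negative"):
        vcv_from_tree(t2)


def test_scale_and_invert_identities(three_taxon_tree):
    V = vcv_from_tree(three_taxon_tree, taxon_order=["A", "B", "C"])
    S, inv = scale_and_invert(V)
    assert np.allclose(S, [[1, 0.5, 0], [0.5, 1, 0], [0, 0, 1]])
    assert np.abs(S @ inv - np.eye(3)).max() < 1e-10
    S2, inv2 = scale_and_invert(4.0 * np.eye(5))
    assert np.allclose(S2, np.eye(5)) and np.allclose(inv2, np.eye(5))


def test_scale_and_invert_guards():
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
    with pytest.raises(ValueError, match="minor"):
        scale_and_invert(bad)
    near = np.array([[1.0, 1.0 - 1e-13], [1.0 - 1e-13, 1.0]])
    with pytest.warns(UserWarning, match="near-singular"):
        scale_and_invert(near)
    with pytest.raises(ValueError, match="near-singular"):
        scale_and_invert(near, strict=True)


def test_vcv_array_reconstruction_invariant():
    ts = simulate_tree_set(ComparativeSimConfig(n_taxa=6, n_trees=8, seed=1))
    arr = build_vcv_array(ts)
    assert arr.n_trees == 8
    for q in range(8):
        err = np.abs(
            arr.scaled[:, :, q] @ arr.omega[:, :, q] - np.eye(6)
        ).max()
        assert err < 1e-8


# -- selection regression ---------------------------------------------------

def test_classify_indicator_thresholds():
    assert classify_indicator(0.75) == "important"
    assert classify_indicator(0.25) == "unimportant"
    assert classify_indicator(0.50) == "inconclusive"
    assert classify_indicator(1.0) == "important"
    assert classify_indicator(0.0) == "unimportant"
    with pytest.raises(ValueError):
        classify_indicator(1.2)


def test_taxon_order_mismatch_is_an_error():
    cfg = ComparativeSimConfig(n_taxa=5, n_trees=2, seed=0)
    ts = simulate_tree_set(cfg)
    data, _ = simulate_trend_data(ts, cfg)
    omega = build_vcv_array(ts, taxon_order=list(reversed(data.taxa)))
    with pytest.raises(ValueError, match="order mismatch"):
        fit_bvs_regression(data, omega, BVSConfig(draws=10, warmup=0))


def test_gls_reduction_single_star_tree():
    """Indicators fixed on, one tree, no iid term: posterior means match the
    closed-form GLS estimate (X'C^-1X)^-1 X'C^-1 y."""
    rng = np.random.default_rng(3)
    M = 12
    taxa = [f"t{i}" for i in range(M)]
    ts = star_tree_set(taxa)
    X = rng.normal(size=(M, 2))
    y = 0.5 * X[:, 0] - 0.8 * X[:, 1] + rng.normal(0, 0.4, M)
    df = pd.DataFrame({"taxon": taxa, "trend": y, "x1": X[:, 0], "x2": X[:, 1]})
    data = ComparativeDataset(df=df, covariates=["x1", "x2"])
    omega = build_vcv_array(ts, taxon_order=taxa)
    cfg = BVSConfig(chains=2, draws=4000, warmup=1000, seed=11,
                    include_eps=False, standardize=True,
                    fix_indicators={"x1": 1, "x2": 1})
    post = fit_quietly(fit_bvs_regression, data, omega, cfg)

    ys, Xs, _ = data.standardized()
    Xd = np.column_stack([np.ones(M), Xs])
    gls = np.linalg.solve(Xd.T @ Xd, Xd.T @ ys)  # C = I on a star tree
    beta = post.draws["beta"].reshape(-1, 2)
    mc_se = beta.std(axis=0) / 20  # generous multiple of the MC error
    for c in range(2):
        assert beta[:, c].mean() == pytest.approx(gls[c + 1],
                                                  abs=max(0.04, 6 * mc_se[c]))


def test_selection_flags_the_active_covariate():
    cfg = ComparativeSimConfig(seed=5)
    ts = simulate_tree_set(cfg)
    data, _ = simulate_trend_data(ts, cfg)
    omega = build_vcv_array(ts, taxon_order=data.taxa)
    post = fit_quietly(
        fit_bvs_regression, data, omega,
        BVSConfig(chains=2, draws=2500, warmup=800, seed=1),
    )
    pm = post.indicator_means
    assert pm["yellow_sea_reliance"] >= 0.75
    assert (pm.drop("yellow_sea_reliance") <= 0.25).all()


def test_tree_mixing_invariance_identical_trees():
    """With all R trees identical the fit matches the single-tree fit."""
    cfg = ComparativeSimConfig(n_taxa=8, n_trees=1, seed=6)
    ts1 = simulate_tree_set(cfg)
    data, _ = simulate_trend_data(ts1, cfg)
    nwk = ts1.trees[0].as_string(schema="newick")
    from flywaytrends.datasets import TreeSet

    tsR = TreeSet(trees=dendropy.TreeList.get(
        data=nwk * 10, schema="newick", rooting="default-rooted"
    ))
    om1 = build_vcv_array(ts1, taxon_order=data.taxa)
    omR = build_vcv_array(tsR, taxon_order=data.taxa)
    cfg_fit = BVSConfig(chains=2, draws=3000, warmup=800, seed=4)
    p1 = fit_quietly(fit_bvs_regression, data, om1, cfg_fit)
    pR = fit_quietly(fit_bvs_regression, data, omR, cfg_fit)
    b1 = p1.draws["beta"].reshape(-1, 5).mean(axis=0)
    bR = pR.draws["beta"].reshape(-1, 5).mean(axis=0)
    assert np.allclose(b1, bR, atol=0.08)


def test_null_indicators_drift_toward_prior_as_noise_grows():
    """With no signal, indicators stay below the importance threshold, and
    as noise swamps the likelihood (unstandardized fit, so the residual
    scale is free) the inclusion probability climbs back toward the
    Bernoulli(1/2) prior: the data stop discriminating."""
    means = {}
    for s2 in (0.5, 1e5):
        cfg = ComparativeSimConfig(
            n_taxa=10, n_trees=5, true_indicators=(0,) * 5,
            residual_variance=s2, trend_mean=0.0, trend_sd=1.0,
            seed=8,
        )
        ts = simulate_tree_set(cfg)
        data, _ = simulate_trend_data(ts, cfg)
        omega = build_vcv_array(ts, taxon_order=data.taxa)
        post = fit_quietly(
            fit_bvs_regression, data, omega,
            BVSConfig(chains=2, draws=2000, warmup=600, seed=2,
                      standardize=False),
        )
        means[s2] = post.indicator_means
    assert (means[0.5] < 0.75).all()
    assert (means[1e5] < 0.75).all()
    # noise-dominated fit sits at the prior; informative fit well below it
    assert means[1e5].mean() > means[0.5].mean()
    assert abs(means[1e5].mean() - 0.5) < 0.1


def test_two_stage_refit_reclassifies_and_sharpens():
    cfg = ComparativeSimConfig(seed=12)
    ts = simulate_tree_set(cfg)
    data, _ = simulate_trend_data(ts, cfg)
    omega = build_vcv_array(ts, taxon_order=data.taxa)
    rep = fit_quietly(
        two_stage_selection, data, omega,
        BVSConfig(chains=2, draws=2500, warmup=800, seed=3),
    )
    assert rep.stage1_classification["yellow_sea_reliance"] == "important"
    assert "yellow_sea_reliance" in rep.retained.index
    # nulls fixed to zero in stage 2
    s2 = rep.stage2
    for cov in s2.covariates:
        if rep.stage1_classification[cov] == "unimportant":
            assert s2.indicator_means[cov] == 0.0
    # retained covariate at least as sharp as in stage 1
    sd1 = rep.stage1.coefficient_summary().loc["yellow_sea_reliance", "sd"]
    sd2 = rep.retained.loc["yellow_sea_reliance", "sd"]
    assert sd2 <= sd1 * 1.25


def test_two_stage_table1_reliance_slope(table1_reliance_data):
    """Nine-taxon report-table fixture, star tree: the retained reliance
    slope (conditional on inclusion) reproduces the published -0.92."""
    data = table1_reliance_data
    ts = star_tree_set(data.taxa)
    omega = build_vcv_array(ts, taxon_order=data.taxa)
    rep = fit_quietly(
        two_stage_selection, data, omega,
        BVSConfig(chains=3, draws=4000, warmup=1000, seed=2),
    )
    slope = rep.retained.loc["yellow_sea_reliance", "slope"]
    assert slope == pytest.approx(-0.92, abs=0.1)


def test_all_null_two_stage_warns_intercept_only():
    cfg = ComparativeSimConfig(
        n_taxa=8, n_trees=2, true_indicators=(0,) * 5,
        residual_variance=1.0, seed=21,
    )
    ts = simulate_tree_set(cfg)
    data, _ = simulate_trend_data(ts, cfg)
    omega = build_vcv_array(ts, taxon_order=data.taxa)
    rep = fit_quietly(
        two_stage_selection, data, omega,
        BVSConfig(chains=2, draws=1500, warmup=500, seed=3),
    )
    if rep.intercept_only:
        assert len(rep.retained) == 0
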