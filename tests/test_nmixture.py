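"""N-mixture model fitting, diagnostics and derived quantities."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from flywaytrends.datasets import CountDataset
from flywaytrends.nmixture import (
    ConvergenceError,
    NmixtureSpec,
    derive_total_abundance,
    fit_flyway_model,
    fit_node_model,
    node_trend_odds_ratios,
    posterior_predictive_check,
)
from flywaytrends.synthetic import CountSimConfig, simulate_counts
from tests.conftest import fit_quietly

SMALL_SPEC = dict(chains=2, draws=500, warmup=400, thin=2)


@pytest.fixture(scope="module")
def small_node_fit():
    cfg = CountSimConfig(
        n_nodes=2, n_sites_per_node=3, n_years=10,
        node_intercepts=(3.6, 3.3), node_trends=(-0.05, -0.05),
        replicates_per_year=(2, 3), seed=10,
    )
    data, truth = simulate_counts(cfg)
    spec = NmixtureSpec(variant="node", seed=5, **SMALL_SPEC)
    return data, truth, fit_quietly(fit_node_model, data, spec)


def test_posterior_latent_abundance_dominates_counts(small_node_fit):
    """Every retained latent N draw is at least the site-year's max count."""
    data, _, fit = small_node_fit
    arr = fit.arrays
    max_c = np.where(arr["M"], arr["C"], 0).max(axis=1)
    N = fit.draws["N"].reshape(-1, arr["C"].shape[0])
    assert (N >= max_c[None, :]).all()
    P = fit.draws["p"]
    assert ((P > 0) & (P < 1)).all()
    assert np.isfinite(fit.draws["loglam"]).all()


def test_node_fit_recovers_equal_trends(small_node_fit):
    data, truth, fit = small_node_fit
    b = fit.beta_draws()
    for k in range(2):
        lo, hi = np.quantile(b[:, k], [0.025, 0.975])
        assert lo - 0.02 < -0.05 < hi + 0.02


def test_seeded_reproducibility(small_counts):
    data, _ = small_counts
    spec = NmixtureSpec(variant="flyway", seed=9, **SMALL_SPEC)
    f1 = fit_quietly(fit_flyway_model, data, spec)
    f2 = fit_quietly(fit_flyway_model, data,
                     NmixtureSpec(variant="flyway", seed=9, **SMALL_SPEC))
    assert np.array_equal(f1.beta_draws(), f2.beta_draws())
    assert np.array_equal(f1.draws["N"], f2.draws["N"])
    s1 = f1.summary(override=True)
    s2 = f2.summary(override=True)
    pd.testing.assert_frame_equal(s1, s2)


def test_known_detection_limit_tracks_poisson_mle():
    """With P fixed at ~1 the posterior mean abundance matches the Poisson
    MLE (the observed counts themselves)."""
    cfg = CountSimConfig(
        n_nodes=1, n_sites_per_node=2, n_years=6,
        node_intercepts=(3.8,), node_trends=(0.0,),
        site_effect_sd=0.0, overdispersion_sd=0.0, detection_re_sd=0.0,
        detection_year_mean=lambda K: np.full(K, 8.0),  # P ~ 0.9997
        replicates_per_year=(2, 2), seed=2,
    )
    data, truth = simulate_counts(cfg)
    spec = NmixtureSpec(variant="flyway", seed=1, **SMALL_SPEC)
    fit = fit_quietly(fit_flyway_model, data, spec)
    arr = fit.arrays
    mle = np.where(arr["M"], arr["C"], 0).max(axis=1)
    N = fit.draws["N"].reshape(-1, arr["C"].shape[0]).mean(axis=0)
    assert np.abs(N - mle).mean() < 1.5


def test_single_site_flyway_warns_but_fits():
    cfg = CountSimConfig(
        n_nodes=1, n_sites_per_node=1, n_years=8,
        node_intercepts=(3.5,), node_trends=(0.0,),
        replicates_per_year=(2, 2), seed=3,
    )
    data, _ = simulate_counts(cfg)
    spec = NmixtureSpec(variant="flyway", seed=1, chains=2, draws=200,
                        warmup=200, thin=2)
    with pytest.warns(UserWarning, match="single-site"):
        fit = fit_flyway_model(data, spec)
    assert np.isfinite(fit.beta_draws()).all()


def test_node_with_single_siteyear_rejected():
    rows = [
        {"site_id": "s1", "node_id": "n1", "year": y, "month": m, "count": 5}
        for y in (2000, 2001, 2002) for m in (1, 2)
    ]
    rows.append({"site_id": "s2", "node_id": "n2", "year": 2000,
                 "month": 1, "count": 3})
    data = CountDataset(pd.DataFrame(rows))
    with pytest.raises(ValueError, match="n2"):
        fit_node_model(data, NmixtureSpec(variant="node", chains=2,
                                          draws=10, warmup=10))


def test_summary_gate_on_convergence(small_node_fit):
    _, _, fit = small_node_fit
    if not fit.converged:
        with pytest.raises(ConvergenceError):
            fit.summary()
    summ = fit.summary(override=True)
    assert {"mean", "sd", "lo", "hi", "rhat"}.issubset(summ.columns)
    assert summ.loc["sigma_omega", "mean"] > 0


# -- posterior predictive check --------------------------------------------

def test_ppc_forced_ties_give_half(small_node_fit):
    """Replicate counts forced identical to observed -> p = 0.5 exactly."""
    data, _, fit = small_node_fit

    class _TiedRng:
        def binomial(self, n, p):
            return np.broadcast_to(fit.arrays["C"][None], p.shape).copy()

    p = posterior_predictive_check(fit, data, rng=_TiedRng())
    assert p == 0.5


def test_ppc_near_half_under_generating_model(small_node_fit):
    data, _, fit = small_node_fit
    p = posterior_predictive_check(fit, data, seed=0)
    assert 0.05 < p < 0.95


def test_ppc_mean_near_half_across_replicates():
    """Calibration: fitting the generating model, the Bayesian p-value
    averages near 0.5 over replicate simulated datasets."""
    ps = []
    for rep in range(30):
        cfg = CountSimConfig(
            n_nodes=2, n_sites_per_node=2, n_years=8,
            node_intercepts=(3.5, 3.2), node_trends=(-0.03, 0.0),
            replicates_per_year=(2, 3), seed=300 + rep,
        )
        data, _ = simulate_counts(cfg)
        spec = NmixtureSpec(variant="flyway", chains=2, draws=400,
                            warmup=300, thin=2, seed=400 + rep)
        fit = fit_quietly(fit_flyway_model, data, spec)
        ps.append(posterior_predictive_check(fit, data, seed=rep))
    assert 0.35 <= np.mean(ps) <= 0.65


def test_ppc_sensitivity_profile_under_misspecification():
    """What the chi-square check can and cannot see.

    The replicate-level detection effect delta_ijt makes the observation
    model nearly saturated: replicate zero-inflation is absorbed into a
    grossly inflated sigma_delta rather than flagged by the p-value. What
    the check does react to is within-site-year underdispersion (replicate
    counts carrying less than binomial spread, e.g. duplicated surveys),
    which no detection effect can mimic: the p-value drops well below 0.5.
    """
    shifted = []
    for rep in range(4):
        cfg = CountSimConfig(
            n_nodes=2, n_sites_per_node=2, n_years=8,
            node_intercepts=(4.5, 4.3), node_trends=(0.0, 0.0),
            replicates_per_year=(5, 5), seed=700 + rep,
        )
        data, _ = simulate_counts(cfg)
        df = data.df.copy()
        df["count"] = df.groupby(["site_id", "year"])["count"] \
            .transform("first")
        spoiled = CountDataset(df)
        spec = NmixtureSpec(variant="flyway", chains=2, draws=400,
                            warmup=300, thin=2, seed=600 + rep)
        fit = fit_quietly(fit_flyway_model, spoiled, spec)
        shifted.append(posterior_predictive_check(fit, spoiled, seed=rep))
    assert np.mean(shifted) < 0.3
    assert sum(p < 0.3 for p in shifted) >= 3

    # zero-inflation is absorbed by the detection effects instead
    cfg = CountSimConfig(
        n_nodes=2, n_sites_per_node=2, n_years=8,
        node_intercepts=(3.8, 3.6), node_trends=(0.0, 0.0),
        replicates_per_year=(3, 3), seed=500,
    )
    data, _ = simulate_counts(cfg)
    df = data.df.copy()
    rng = np.random.default_rng(0)
    df.loc[rng.random(len(df)) < 0.5, "count"] = 0
    spoiled = CountDataset(df)
    spec = NmixtureSpec(variant="flyway", chains=2, draws=400,
                        warmup=300, thin=2, seed=601)
    fit = fit_quietly(fit_flyway_model, spoiled, spec)
    assert fit.draws["sigma_delta"].mean() > 2.0  # vs ~0.2 when well specified


def test_ppc_requires_latent_draws(small_node_fit):
    data, _, fit = small_node_fit
    crippled = dict(fit.draws)
    crippled.pop("N")
    from dataclasses import replace

    with pytest.raises(ValueError, match="latent"):
        posterior_predictive_check(replace(fit, draws=crippled), data)


# -- odds ratios and totals --------------------------------------------------

def test_odds_ratio_identities(small_node_fit):
    data, truth, fit = small_node_fit
    orr = node_trend_odds_ratios(fit)
    ab = orr.set_index(["node_a", "node_b"])
    pairs = [(a, b) for a in fit.node_labels for b in fit.node_labels if a != b]
    assert set(ab.index) == set(pairs)
    a, b = fit.node_labels[:2]
    r_ab = np.exp(fit.beta_draws()[:, 0] - fit.beta_draws()[:, 1])
    r_ba = np.exp(fit.beta_draws()[:, 1] - fit.beta_draws()[:, 0])
    assert np.allclose(r_ab * r_ba, 1.0)
    assert ab.loc[(a, b), "mean"] == pytest.approx(r_ab.mean())
    # equal true trends: ratio CRI straddles 1
    assert ab.loc[(a, b), "lo"] < 1 < ab.loc[(a, b), "hi"]


def test_odds_ratio_needs_two_nodes(small_counts):
    data, _ = small_counts
    spec = NmixtureSpec(variant="flyway", seed=0, chains=2, draws=100,
                        warmup=100)
    fit = fit_quietly(fit_flyway_model, data, spec)
    with pytest.raises(ValueError, match="2 nodes"):
        node_trend_odds_ratios(fit)


def test_total_abundance_thinning_correction():
    """With detection near 0.5 the detection-corrected totals average about
    twice the raw mean counts. Detection placement is noisy per dataset
    (the classic lambda-p ridge), so the oracle is checked on the average
    over replicate simulations."""
    ratios = []
    for rep in range(5):
        cfg = CountSimConfig(
            n_nodes=1, n_sites_per_node=8, n_years=8,
            node_intercepts=(4.2,), node_trends=(0.0,),
            site_effect_sd=0.2, overdispersion_sd=0.05, detection_re_sd=0.05,
            detection_year_mean=lambda K: np.full(K, logit(0.5)),
            replicates_per_year=(3, 4), seed=100 + rep,
        )
        data, truth = simulate_counts(cfg)
        spec = NmixtureSpec(variant="flyway", seed=2 + rep, **SMALL_SPEC)
        fit = fit_quietly(fit_flyway_model, data, spec)
        totals = derive_total_abundance(fit, seed=0)
        raw = data.df.groupby("year")["count"].mean() * 8
        ratio = (totals.set_index("year")["mean"] / raw).mean()
        ratios.append(ratio)
        assert ratio > 1.1  # correction always upward
        assert (totals["lo"] <= totals["mean"]).all()
        assert (totals["mean"] <= totals["hi"]).all()
    assert 1.4 < np.mean(ratios) < 2.6


def test_total_abundance_matches_truth_under_perfect_detection():
    cfg = CountSimConfig(
        n_nodes=1, n_sites_per_node=3, n_years=5,
        node_intercepts=(4.0,), node_trends=(0.0,),
        site_effect_sd=0.0, overdispersion_sd=0.0, detection_re_sd=0.0,
        detection_year_mean=lambda K: np.full(K, 8.0),
        replicates_per_year=(2, 2), seed=4,
    )
    data, truth = simulate_counts(cfg)
    spec = NmixtureSpec(variant="flyway", seed=2, **SMALL_SPEC)
    fit = fit_quietly(fit_flyway_model, data, spec)
    totals = derive_total_abundance(fit, seed=0)
    true_totals = truth["N"].sum(axis=0)
    assert np.abs(totals["mean"].to_numpy() - true_totals).max() < \
        0.05 * true_totals.mean() + 5


def test_latent_uncertainty_shrinks_with_more_replicates():
    """Information monotonicity, checked exactly: the conditional
    distribution of latent N given the counts narrows as replicates are
    added (enumeration over the latent grid, no sampling)."""
    lam, p = 50.0, 0.55
    counts_seq = [[30], [30, 28], [30, 28, 33, 29]]
    sds = []
    for counts in counts_seq:
        N = np.arange(max(counts), 400)
        from scipy.stats import binom, poisson

        logw = poisson.logpmf(N, lam)
        for c in counts:
            logw = logw + binom.logpmf(c, N, p)
        w = np.exp(logw - logw.max())
        w /= w.sum()
        mean = (w * N).sum()
        sds.append(np.sqrt((w * (N - mean) ** 2).sum()))
    assert sds[0] > sds[1] > sds[2]
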