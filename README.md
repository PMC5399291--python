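# flywaytrends

Detection-corrected population trends for migratory shorebirds of the East
Asian–Australasian Flyway (EAAF), and a phylogenetic comparative analysis of
what drives those trends.

Millions of shorebirds that spend the non-breeding season in Australia and
New Zealand refuel on Yellow Sea tidal mudflats during migration — a
rapidly shrinking ecosystem. This package implements the two-stage analysis
used to ask whether reliance on that stopover region predicts population
decline:

1. **N-mixture trend models** (`flywaytrends.nmixture`). Replicated counts
   `c_ijt` at site *i*, monthly replicate *j*, year *t* are binomial
   thinnings of a latent Poisson abundance,

       N_it ~ Poisson(λ_it),   c_ijt | N_it ~ Binomial(N_it, P_ijt)
       log λ_it  = ω_i + α_k + β_k (t − t*) + ε_it
       logit P_ijt = γ_t + δ_ijt

   fitted by MCMC in a node-level form (trend β_k per non-breeding region)
   and a flyway form (single β per taxon), with chi-square posterior
   predictive checks, pairwise node odds ratios and detection-corrected
   annual abundance totals. The latent N is marginalized out of the
   likelihood over a truncated window (numba-compiled kernels), so small
   instances can be checked exactly against brute-force enumeration.

2. **Bayesian variable selection over a tree set**
   (`flywaytrends.phylo`). Taxon trends `Td_z` are regressed on Yellow Sea
   reliance and four life-history covariates with Brownian-motion
   phylogenetic residual covariance, integrating over R ultrametric trees
   (one tree index drawn per MCMC iteration):

       Td ~ MVN(α + X (v ∘ θ), σ² C_q + σ_ε² I),   v_c ~ Bernoulli(1/2)

   Indicator posterior means classify covariates (≥0.75 important, ≤0.25
   unimportant); a two-stage refit pins unimportant indicators to zero.

Because the underlying count data are held by monitoring organizations
under restricted agreements, `flywaytrends.synthetic` generates datasets
with known ground truth that match the assumed statistical structure
(sites nested in four non-breeding nodes, 20 years, 1–5 monthly replicates,
detection ≈ 0.52–0.68), and the published flyway trend table ships as a
packaged fixture (`flywaytrends.load_table1()`). See `docs/methods.md` for
models, priors, sampler design and limitations.

## Worked example

```python
import numpy as np
from flywaytrends import (
    CountSimConfig, simulate_counts, NmixtureSpec, fit_flyway_model,
    posterior_predictive_check, TrendTable, trend_report,
)

# simulate a taxon declining 4% per year at 16 sites x 20 years
data, truth = simulate_counts(CountSimConfig(node_trends=(-0.04,) * 4, seed=11))
fit = fit_flyway_model(data, NmixtureSpec(variant="flyway", seed=3))
beta = fit.beta_draws()[:, 0]
print(f"trend {beta.mean():.4f} (95% CRI {np.quantile(beta, 0.025):.4f}, "
      f"{np.quantile(beta, 0.975):.4f})")
print(f"PPC p-value {posterior_predictive_check(fit, data, seed=1):.2f}")

rep = trend_report(TrendTable.from_table1())
print({k: (round(float(v), 2) if isinstance(v, float) else v)
       for k, v in rep.items()})
```

prints (the fitted trend recovers the simulated −0.04; a PPC p-value near
0.5 indicates adequate fit; the report reproduces the published summary
quantities from the packaged table):

```
trend -0.0445 (95% CRI -0.0546, -0.0365)
PPC p-value 0.52
{'n_taxa': 10, 'n_credible_declines': 7, 'low_group_mean_pct': -0.93,
 'high_group_mean_pct': -5.19, 'reliance_slope': -0.92,
 'reliance_slope_lo': -1.27, 'reliance_slope_hi': -0.58}
```

Seven of the ten taxa decline credibly; taxa with ≥50% Yellow Sea reliance
decline at −5.2%/yr on average versus −0.9%/yr for low-reliance taxa, and
the standardized reliance–trend slope is −0.92.

A command-line surface wraps the same functions:

```sh
flywaytrends simulate --seed 1 --out-dir sim/
flywaytrends fit-counts sim/counts.csv --variant flyway --seed 1
flywaytrends fit-comparative --trees trees.nwk --data comp.csv
flywaytrends report
flywaytrends run-all --seed 1 --small   # end-to-end synthetic pipeline
```

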