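# Methods

This note documents the statistical models, priors, samplers and numerical
choices behind `flywaytrends`, and what the synthetic-data tests do and do
not establish about real monitoring data.

## Stage 1: detection-corrected abundance and trends

### Model

Replicated non-breeding-season counts `c_ijt` (site i, monthly replicate j,
year t) are modelled as binomial thinnings of a latent Poisson abundance:

    N_it ~ Poisson(lambda_it)
    c_ijt | N_it ~ Binomial(N_it, P_ijt)

Expected log abundance is log-linear in the year, centred on the mean year
t* so intercepts are mid-series abundances:

    node form:   log lambda_it = omega_i + alpha_k + beta_k (t - t*) + eps_it
    flyway form: log lambda_it = omega_i + alpha   + beta   (t - t*) + eps_it

`omega_i` is a site random effect (sites differ persistently in size),
`alpha_k`/`beta_k` are intercept and per-year log-scale trend for
non-breeding node k (the flyway form pools all sites into a single trend),
and `eps_it` absorbs extra-Poisson dispersion per site-year. Detection is

    logit P_ijt = gamma_t + delta_ijt

with a yearly mean level `gamma_t` and a replicate-level random effect
`delta_ijt`. The logit link is stated explicitly in configuration: it is
the standard choice that makes `gamma_t` interpretable as a yearly mean
detection probability. Detection carries no covariates.

Model assumptions: within-season closure at each site; equal detectability
of individuals within a taxon; Poisson/binomial parametric forms (checked
by the posterior predictive test below); negligible double counting.

### Priors

* `omega_i ~ N(0, s_omega^2)`, `eps_it ~ N(0, s_eps^2)` with
  `s^2 ~ inverse-gamma(1e-3, 1e-3)` — equivalently precision ~
  gamma(1e-3, 1e-3), the conventional vague hierarchical prior.
* `alpha_k`, `beta_k`, `gamma_t ~ N(0, 1e3)`. Intercepts and trends are
  fixed effects; giving them estimated variance hyperpriors would act as a
  1/|beta| shrinkage prior when a group has one or few members (the flyway
  variant has exactly one trend) and measurably biased recovered trends
  toward zero in simulation, so they get fixed vague priors instead.
* `delta_ijt ~ N(0, s_delta^2)` with `s_delta ~ Uniform(0, 100)`. A
  literal `delta ~ Uniform(0, 100)` variant is available via
  `delta_prior="literal_uniform"` for sensitivity analysis; on the logit
  scale it forces detection toward 1 and is not a usable default.

### Likelihood: marginalization over N

The latent abundance is summed out of the likelihood per site-year:

    L = sum_{N >= max_j c_j} Pois(N | lambda) prod_j Bin(c_j | N, p_j)

computed in log space over a per-site-year window. The lower end is the
maximum observed count (the binomial pmf vanishes below it); the upper end
is a generous Poisson upper tail at the data-implied abundance scale
(`n_max_factor * lambda_hat + 6 sqrt(lambda_hat) + n_max_pad`, with
`lambda_hat` = mean count / 0.55). A doubling utility
(`likelihood.converged_n_max`) verifies that widening a window changes the
log-likelihood by less than 1e-8. Inside a window the summand is
log-concave in N, so only terms within 37 nats of the mode are
exponentiated. Marginalization (rather than sampling N directly) keeps all
sampled parameters continuous and lets brute-force enumeration act as an
exact oracle: the test suite checks agreement to 1e-10 on small instances.

Missing replicates are simply absent from the product over j — the
likelihood-exact treatment, with no imputation. Replicates within a
site-year are treated as exchangeable.

### Sampler

Fitting uses an adaptive Metropolis-within-Gibbs scheme (numba-compiled
likelihood kernels):

* vectorized random-walk updates on conditionally independent blocks
  (sites, nodes, site-years, years, replicate columns), step sizes adapted
  during warmup to ~44% acceptance;
* conjugate inverse-gamma Gibbs draws for the random-effect variances;
* exact Gibbs *recentering* moves along likelihood-invariant directions of
  the hierarchy (site effects vs node intercepts, dispersion vs intercepts
  and trends, replicate detection effects vs yearly levels) — without
  these, fixed effects and random-effect means mix extremely slowly;
* joint *ridge* proposals along the abundance-detection trade-off
  (`lambda * P` is far better identified than either factor): all
  intercepts up while yearly detection levels move down by a fixed factor
  of 2.5 (~ d logit p / d log lambda at p = 0.6), and the analogous move
  along the centred-year direction for trends;
* *interweaving* scale moves that multiply a random-effect vector and its
  variance jointly, fixing the classic slow mixing of variance
  hyperparameters near small values.

Latent `N_it` is drawn from its exact discrete conditional at each retained
draw, so posterior predictive checks and abundance totals use full latent
posteriors. Convergence is monitored by split-R̂ (via ArviZ) on all
intercepts, trends, yearly detection levels and standard deviations;
`summary()` refuses to report when any monitored R̂ exceeds 1.1 unless
overridden. The published MCMC settings (3 chains x 800,000 iterations,
200,000 burn-in, thin 18) are available as `NmixtureSpec.paper_preset()`;
the desk-scale default (3 chains x 2,000 kept draws after 1,500 warmup
sweeps) is sized for the adaptive sampler, which needs far fewer
iterations than a generic Gibbs sampler.

### Posterior predictive check

For each retained draw the chi-square discrepancy
`sum (c - N P)^2 / (N P + 0.5)` is computed for the observed counts and for
replicate counts drawn `Binomial(N, P)` from the same draw; the Bayesian
p-value is the proportion of draws where the observed discrepancy exceeds
the replicate one (ties counted half). Near 0.50 indicates adequate fit.

A property worth knowing: because `delta_ijt` gives every replicate its own
detection effect, the observation model is nearly saturated. Gross
zero-inflation is therefore *absorbed* (the posterior of `s_delta` inflates
by an order of magnitude) rather than flagged by the p-value. What the
check does react to is within-site-year underdispersion — replicate counts
with less than binomial spread, e.g. duplicated surveys — which no
detection effect can mimic. The test suite encodes exactly this
sensitivity profile, and a large `s_delta` posterior should itself be read
as a red flag.

### Derived quantities

* **Annual totals**: per-year sums of latent `N_it` over sites, posterior
  mean and 95% CRI. Site-years without counts are imputed per draw from
  the fitted model (fresh dispersion noise, Poisson draw) so totals refer
  to the same site set each year.
* **Node odds ratios**: per-draw `exp(beta_a - beta_b)` for node pairs,
  with the mean absolute deviation from 1 in percent as a summary of how
  much trends differ among nodes.
* **Credible trend rule**: a 95% CRI entirely below (above) zero is a
  credible decline (increase); an endpoint exactly at zero is not credible.

## Stage 2: explaining trend variation across taxa

Flyway trend estimates `Td_z` for M taxa are regressed on five taxon-level
covariates (Yellow Sea reliance, migration distance, breeding range size,
generation time, body size) with Brownian-motion phylogenetic residual
covariance. For each tree, the VCV has root-to-tip distance on the
diagonal and MRCA depth off it; scaled to unit height it is a correlation
structure and sigma^2 a residual variance. Tree uncertainty enters through
R trees; one tree index is drawn uniformly per MCMC iteration (a uniform
mixture over the R likelihoods — the standard multi-tree idiom; the mixing
rule is a modelling choice, not a data-determined quantity).

The likelihood is

    Td ~ MVN(alpha + X (v * theta), sigma^2 C_q + sigma_eps^2 I)

Covariates and response are z-scored before fitting (configurable): the
published slope of -0.92 is reproducible only on the standardized scale,
and standardization is what makes a common Bernoulli(1/2) selection prior
comparable across covariates with wildly different units. The i.i.d. error
term is *integrated out analytically* rather than sampled: a sampled
per-taxon error vector absorbs the covariate signal and freezes the
indicators (verified in simulation), while the marginalized form leaves the
selection fully informed. It has its own estimated variance; setting
`include_eps=False` drops it. An optional known-variance measurement-error
extension (adding diag(SE^2) from the stage-1 CRIs) exists behind
`measurement_error=True` but is off by default: the baseline treats the
trend point estimates as data.

Selection uses binary indicators `v_c ~ Bernoulli(1/2)` multiplying
coefficients `theta_c ~ N(0, 1e3)`. The indicator draw is a *collapsed*
Gibbs step: `theta_c` is integrated out under its prior (a rank-1 precision
update), which makes inclusion flips well mixed and path-independent — the
one-at-a-time Kuo–Mallick update is notoriously sticky, and an adaptive
hierarchical coefficient prior makes the chain metastable (both observed
here in simulation before settling on this form). The diffuse coefficient
prior doubles as a strong Occam penalty: a covariate is retained only when
its Bayes factor overcomes the prior spread, which keeps chance
correlations among a handful of taxa from lighting up null covariates.
Intercept and coefficients are conjugate draws; the two variances use
log-scale random-walk Metropolis.

Indicator posterior means classify covariates: >= 0.75 important, <= 0.25
unimportant, otherwise inconclusive. The two-stage procedure refits with
unimportant indicators pinned to zero, sharpening retained predictors.
Coefficient tables report both the marginal effect `E[v theta]` and the
slope conditional on inclusion (`slope`, with CRI) — the latter is the
scale on which a selected predictor's effect is quoted. The published
preset (3 chains x 120,000 / 20,000 burn-in / thin 3) is
`BVSConfig.paper_preset()`; the desk default is 3 x 3,000 kept draws.

Subspecies: the comparative fixture follows the source analysis in using
the *menzbieri* bar-tailed godwit and excluding *baueri* (the tree set has
a single branch for the species); the alternative run is a data-subsetting
choice, not a code path.

## Report summaries

Per-year percent change defaults to `100 * beta` (the small-slope
approximation that reproduces the printed group means of -5.2 and -1.0 %/yr
and "up to 8%" from a slope of -0.075); `100*(exp(beta)-1)` is available
behind a flag and recorded in output metadata. The high-reliance group
boundary is reliance >= 0.50 — including the boundary taxon is the only
membership that reproduces the printed -5.2 — and the low group is
reliance <= 0.40. Group means are computed from posterior-mean trends, with
a +/-0.15 percentage-point tolerance from table rounding in the desk
checks. The tree-free standardized reliance-trend slope equals the Pearson
correlation; its interval is the normal-theory interval of the standardized
slope.

## Synthetic data: what it does and does not emulate

The generator draws counts from exactly the hierarchical process the models
assume: 4 nodes x 4 sites x 20 years by default, 1-5 monthly replicates
per site-year (missing completely at random when a missingness fraction is
set, always keeping one replicate), yearly detection levels wandering
inside ~0.52-0.68 (the empirically reported range), replicate detection
noise of 0.2 on the logit scale, site effects of SD 0.5 and site-year
dispersion of SD 0.15 on the log scale, and node trends spanning 0 to -6%
per year. Default node intercepts (4.0, 3.7, 4.3, 3.4 on the log scale,
i.e. typical site abundances of ~30-75 birds) put the testbed at a desk
scale where a full fit takes seconds to tens of seconds; real roost maxima
are often an order of magnitude larger, which changes compute cost but not
the statistical structure being exercised. Trees are Kingman coalescent
draws rescaled to unit height; comparative responses are MVN draws on the
standardized scale mapped affinely to per-year slope units.

Because the generator matches the model, passing recovery tests establish
*internal* validity (the samplers target the right posterior and the
pipeline recovers truth under the stated assumptions) — they do not test
robustness to closure violations, observer behaviour, tidal timing or
within-season movement, none of which are simulated.

## Known limitations

* The abundance-detection level trade-off (`lambda * P`) leaves absolute
  abundance weakly identified at small designs: across replicate datasets
  of 64 site-years the posterior mean detection ranged ~0.46-0.77 around a
  true 0.5. Trends are far better identified than levels; treat absolute
  totals with correspondingly wide intervals.
* The PPC conservatism described above: misfit channels that the replicate
  detection effect can absorb do not move the p-value.
* Brownian motion is the only residual-evolution model (no OU or lambda
  transforms), matching the analysis being reproduced.
* With ~10 taxa, selection outcomes for weak predictors are sensitive to
  chance covariate correlations; the indicator thresholds (0.75/0.25)
  should be read as the original authors intended — evidence grades, not
  error-controlled tests.
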