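"""Marginalized N-mixture likelihood kernel.

The observation model is a binomial thinning of a latent Poisson abundance:
counts ``c_j`` at one site-year are Binomial(N, p_j) given latent N ~
Poisson(lambda). Summing N out of the joint gives the marginal likelihood

    L(c | lambda, p) = sum_{N >= max(c)} Pois(N | lambda) prod_j Bin(c_j | N, p_j)

computed here in log space over a truncated grid. Marginalization keeps every
sampled quantity continuous and lets brute-force enumeration serve as an exact
oracle on small instances.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit, gammaln, logsumexp


def detection_model(gamma_t: float, delta_ijt: float) -> float:
    """Detection probability: inverse-logit of year mean plus replicate effect.

    ``gamma_t`` is the mean detection level in year t (logit scale) and
    ``delta_ijt`` a site/month/year random effect. Result lies in (0, 1).
    """
    return float(expit(gamma_t + delta_ijt))


def sityear_marginal_loglik(
    counts_j, lam: float, p_j, n_max: int
) -> float:
    """Log marginal likelihood of one site-year's replicate counts.

    Parameters
    ----------
    counts_j
        Nonnegative integer counts for the J replicates.
    lam
        Poisson mean of latent abundance (> 0).
    p_j
        Detection probability per replicate, each in (0, 1]. A scalar is
        broadcast to all replicates.
    n_max
        Truncation point of the latent sum; must be >= max(counts_j).

    Returns
    -------
    float
        log sum_{N=max(c)}^{n_max} Pois(N|lam) prod_j Bin(c_j|N, p_j).
    """
    c = np.asarray(counts_j, dtype=int)
    if c.ndim == 0:
        c = c[None]
    p = np.broadcast_to(np.asarray(p_j, dtype=float), c.shape).copy()
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("detection probabilities must lie in [0, 1]")
    cmax = int(c.max(initial=0))
    if n_max < cmax:
        raise ValueError(f"n_max={n_max} below max observed count {cmax}")
    zero_p = p == 0
    if np.any(zero_p & (c > 0)):
        warnings.warn("p=0 with a positive count: likelihood is zero")
        return -np.inf

    N = np.arange(cmax, n_max + 1)
    log_pois = N * np.log(lam) - lam - gammaln(N + 1)
    log_binom = np.zeros_like(log_pois)
    for cj, pj in zip(c, p):
        if pj == 0:  # c must be 0 here; Bin(0|N,0)=1
            continue
        term = (
            gammaln(N + 1)
            - gammaln(cj + 1)
            - gammaln(N - cj + 1)
            + cj * np.log(pj)
        )
        if pj < 1:
            term = term + (N - cj) * np.log1p(-pj)
        else:
            # p=1: only N == c has mass
            term = np.where(N == cj, 0.0, -np.inf)
        log_binom = log_binom + term
    return float(logsumexp(log_pois + log_binom))


def choose_n_max(counts_j, lam: float, quantile: float = 0.9999) -> int:
    """Truncation rule: max of the observed count and the Poisson upper
    quantile at the current lambda."""
    from scipy.stats import poisson

    cmax = int(np.max(counts_j, initial=0))
    return int(max(cmax, poisson.ppf(quantile, lam)))


def converged_n_max(counts_j, lam: float, p_j, start: int | None = None,
                    tol: float = 1e-8, cap: int = 1_000_000) -> int:
    """Double the truncation point until the marginal log-likelihood changes
    by less than ``tol``; returns the converged n_max."""
    n = start if start is not None else max(choose_n_max(counts_j, lam), 10)
    prev = sityear_marginal_loglik(counts_j, lam, p_j, n)
    while n < cap:
        n2 = 2 * n
        cur = sityear_marginal_loglik(counts_j, lam, p_j, n2)
        if abs(cur - prev) < tol:
            return n2
        prev, n = cur, n2
    warnings.warn(f"n_max doubling hit cap {cap} without converging")
    return n
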