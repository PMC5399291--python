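"""Hierarchical binomial–Poisson N-mixture models for replicated counts.

Counts c_ijt at site i, replicate j, year t are binomial thinnings of a
latent Poisson abundance N_it with detection probability P_ijt:

    N_it ~ Poisson(lambda_it)
    c_ijt | N_it ~ Binomial(N_it, P_ijt)
    log lambda_it = omega_i + alpha_k + beta_k (t - t*) + eps_it   (node form)
    log lambda_it = omega_i + alpha   + beta   (t - t*) + eps_it   (flyway form)
    logit P_ijt  = gamma_t + delta_ijt

omega_i is a site random effect, alpha_k / beta_k intercept and log-linear
trend per non-breeding node, eps_it extra-Poisson dispersion, gamma_t the
yearly mean detection level and delta_ijt a replicate-level detection effect.
The trend covariate is the year centred on its mean t*.

Fitting marginalizes N_it out of the likelihood over a truncated grid
(see :mod:`flywaytrends.likelihood`) and samples all remaining parameters
with an adaptive Metropolis-within-Gibbs scheme: vectorized random-walk
updates on conditionally independent blocks, conjugate inverse-gamma Gibbs
draws for the random-effect variances, exact Gibbs recentering along
likelihood-invariant directions of the hierarchy, joint "ridge" proposals
along the weakly identified abundance-detection trade-off, and interweaving
scale moves that rescale each random-effect vector jointly with its
variance. Latent N_it is re-sampled from its exact conditional at each
retained draw, so posterior predictive checks and abundance totals have
full latent posteriors available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Literal

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .datasets import CountDataset

logger = logging.getLogger(__name__)

_IG_SHAPE = 1e-3
_IG_SCALE = 1e-3
_GAMMA_PRIOR_VAR = 1e3   # yearly detection means: Normal(0, 1e3)
_FIXED_EFFECT_VAR = 1e3  # node intercepts and trends: Normal(0, 1e3)
_DELTA_SD_BOUND = 100.0  # sigma_delta ~ Uniform(0, 100)


class ConvergenceError(RuntimeError):
    pass


@dataclass
class NmixtureSpec:
    """Model variant, priors and MCMC settings.

    ``draws`` counts post-warmup iterations kept per chain (before thinning).
    ``delta_prior`` selects the replicate detection-effect prior:
    ``"hierarchical"`` is delta ~ Normal(0, sigma_delta^2) with
    sigma_delta ~ Uniform(0, 100); ``"literal_uniform"`` places
    Uniform(0, 100) directly on delta for sensitivity analysis.
    """

    variant: Literal["node", "flyway"] = "node"
    chains: int = 3
    draws: int = 2000
    warmup: int = 1500
    thin: int = 2
    seed: int = 0
    delta_prior: Literal["hierarchical", "literal_uniform"] = "hierarchical"
    n_max_factor: float = 2.0
    n_max_pad: int = 45
    n_max_cap: int = 20000
    rhat_threshold: float = 1.1

    @classmethod
    def paper_preset(cls, **kw) -> "NmixtureSpec":
        """3 chains x 800,000 iterations, 200,000 burn-in, thin 18."""
        return cls(chains=3, draws=600_000, warmup=200_000, thin=18, **kw)

    def validate(self) -> None:
        if self.chains < 2:
            raise ValueError(f"need >= 2 chains for diagnostics, got {self.chains}")
        if self.draws < 1 or self.warmup < 0:
            raise ValueError("draws must be >= 1 and warmup >= 0")


@dataclass
class NmixturePosterior:
    """MCMC draws plus data context and convergence diagnostics.

    ``draws`` arrays are (chains, kept, ...): ``alpha``/``beta`` (nodes or 1
    column), ``gamma`` (years), ``omega`` (sites), ``eps``/``loglam``/``N``
    (site-years), ``p`` (site-years x replicates), and variance parameters.
    """

    draws: dict
    arrays: dict
    spec: NmixtureSpec
    variant: str
    diagnostics: pd.Series
    converged: bool

    @property
    def node_labels(self) -> list:
        return self.arrays["nodes"] if self.variant == "node" else ["flyway"]

    def beta_draws(self) -> np.ndarray:
        """Flattened (n_draws, n_nodes) trend draws."""
        b = self.draws["beta"]
        return b.reshape(-1, b.shape[-1])

    def summary(self, override: bool = False, level: float = 0.95) -> pd.DataFrame:
        """Posterior summaries of the monitored parameters.

        Refuses to report when any monitored R-hat exceeds the threshold,
        unless ``override=True``.
        """
        if not self.converged and not override:
            bad = self.diagnostics[self.diagnostics > self.spec.rhat_threshold]
            raise ConvergenceError(
                f"R-hat above {self.spec.rhat_threshold} for: "
                f"{bad.index.tolist()}; rerun longer or pass override=True"
            )
        a = (1 - level) / 2
        rows = []
        for name, labels in self._monitored_items():
            arr = self.draws[name].reshape(self.draws[name].shape[0],
                                           self.draws[name].shape[1], -1)
            for k, lab in enumerate(labels):
                x = arr[:, :, k].ravel()
                rows.append({
                    "parameter": lab,
                    "mean": x.mean(), "sd": x.std(),
                    "lo": np.quantile(x, a), "median": np.quantile(x, 0.5),
                    "hi": np.quantile(x, 1 - a),
                    "rhat": self.diagnostics.get(lab, np.nan),
                })
        return pd.DataFrame(rows).set_index("parameter")

    def _monitored_items(self):
        nodes = self.node_labels
        years = [f"gamma[{int(y)}]" for y in self.arrays["years"]]
        yield "alpha", [f"alpha[{n}]" for n in nodes]
        yield "beta", [f"beta[{n}]" for n in nodes]
        yield "gamma", years
        yield "sigma_omega", ["sigma_omega"]
        yield "sigma_eps", ["sigma_eps"]
        yield "sigma_delta", ["sigma_delta"]


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

class _NmixSampler:
    def __init__(self, arrays: dict, spec: NmixtureSpec, n_nodes: int):
        from . import _kernels as _k

        self._k = _k
        self.spec = spec
        self.C = np.ascontiguousarray(arrays["C"], dtype=np.int64)
        self.M = np.ascontiguousarray(arrays["M"], dtype=np.bool_)
        self.sy_site = arrays["sy_site"]
        self.sy_year = arrays["sy_year"]
        self.site_node = arrays["site_node"]
        self.x_year = arrays["x_year"]
        self.S, self.J = self.C.shape
        self.R = len(arrays["sites"])
        self.K = len(arrays["years"])
        self.nk = n_nodes
        self.sy_node = self.site_node[self.sy_site]
        self.sy_x = self.x_year[self.sy_year]

        # per-row latent windows [max count, generous Poisson upper tail]
        mean_c = np.where(self.M, self.C, 0).sum(axis=1) / self.M.sum(axis=1)
        lam0 = np.maximum(mean_c / 0.55, 0.5)
        self.lam0 = lam0
        self.n0 = self.C.max(axis=1)
        top = np.maximum(
            np.ceil(spec.n_max_factor * lam0 + 6 * np.sqrt(lam0)
                    + spec.n_max_pad).astype(np.int64),
            self.n0 + 30,
        )
        top = np.minimum(top, spec.n_max_cap)
        if np.any(top >= spec.n_max_cap):
            warnings.warn(f"latent-abundance window capped at {spec.n_max_cap}")
        widths = top - self.n0 + 1
        self.ptr = np.zeros(self.S + 1, dtype=np.int64)
        np.cumsum(widths, out=self.ptr[1:])
        self.total = int(self.ptr[-1])
        self.nvals = np.concatenate(
            [np.arange(self.n0[s], top[s] + 1) for s in range(self.S)]
        ).astype(np.float64)
        self.lgfact = gammaln(self.nvals + 1)
        self.logcoef = np.zeros((self.total, self.J))
        for s in range(self.S):
            a, b = self.ptr[s], self.ptr[s + 1]
            n = self.nvals[a:b]
            for j in range(self.J):
                if self.M[s, j]:
                    c = self.C[s, j]
                    self.logcoef[a:b, j] = (
                        gammaln(n + 1) - gammaln(c + 1) - gammaln(n - c + 1)
                    )
        self.all_rows = np.arange(self.S, dtype=np.int64)
        self.rows_j = [
            np.flatnonzero(self.M[:, j]).astype(np.int64) for j in range(self.J)
        ]
        # scratch buffers
        self._marg_buf = np.empty(self.S)
        self._Lb_scr = np.empty((self.total, self.J))
        self._B_scr = np.empty(self.total)
        self._Lbcol_scr = np.empty(self.total)
        self._Nout = np.empty(self.S)
        self._win_scr = np.empty(int(widths.max()))
        self._rows_by_year = [
            np.flatnonzero(self.sy_year == t) for t in range(self.K)
        ]
        self._rows_by_node = [
            np.flatnonzero(self.sy_node == k) for k in range(self.nk)
        ]
        self._sites_by_node = [
            np.flatnonzero(self.site_node == k) for k in range(self.nk)
        ]
        self._rows_by_site = [
            np.flatnonzero(self.sy_site == i) for i in range(self.R)
        ]

    # -- state ------------------------------------------------------------
    def init_state(self, rng: np.random.Generator):
        st = {}
        p0 = 0.6
        mean_c = np.where(self.M, self.C, 0).sum(axis=1) / self.M.sum(axis=1)
        loglam0 = np.log(np.maximum(mean_c / p0, 0.5))
        alpha0 = np.array([
            loglam0[self.sy_node == k].mean() if np.any(self.sy_node == k) else 0.0
            for k in range(self.nk)
        ])
        omega0 = np.array([
            loglam0[self.sy_site == i].mean() - alpha0[self.site_node[i]]
            if np.any(self.sy_site == i) else 0.0
            for i in range(self.R)
        ])
        st["omega"] = omega0 + rng.normal(0, 0.05, self.R)
        st["alpha"] = alpha0 + rng.normal(0, 0.05, self.nk)
        st["beta"] = rng.normal(0, 0.005, self.nk)
        st["eps"] = np.clip(
            loglam0 - st["omega"][self.sy_site] - st["alpha"][self.sy_node],
            -1.5, 1.5,
        ) * 0.5
        st["gamma"] = np.full(self.K, np.log(p0 / (1 - p0))) + rng.normal(0, 0.05, self.K)
        st["delta"] = np.zeros((self.S, self.J))
        st["s2_om"] = 0.25
        st["s2_al"] = _FIXED_EFFECT_VAR
        st["s2_be"] = _FIXED_EFFECT_VAR
        st["s2_ep"] = 0.05
        st["s2_de"] = 0.05
        self._refresh_caches(st)
        return st

    def _loglam(self, st):
        return (st["omega"][self.sy_site] + st["alpha"][self.sy_node]
                + st["beta"][self.sy_node] * self.sy_x + st["eps"])

    def _refresh_caches(self, st):
        st["loglam"] = self._loglam(st)
        st["lam"] = np.exp(st["loglam"])
        st["p"] = expit(st["gamma"][self.sy_year][:, None] + st["delta"])
        st["Lb"] = np.empty((self.total, self.J))
        st["B"] = np.empty(self.total)
        self._k.binom_table(st["p"], self.C, self.M, self.logcoef,
                            self.nvals, self.ptr, st["Lb"], st["B"])
        st["marg"] = np.empty(self.S)
        self._k.marg_rows(st["loglam"], st["lam"], st["B"], self.ptr,
                          self.nvals, self.lgfact, self.all_rows,
                          self._win_scr, st["marg"])

    # -- update blocks ----------------------------------------------------
    def _accept_lam(self, st, loglam_new, group, ngroups, dprior, rng):
        loglam_new = np.clip(loglam_new, -30, 30)
        lam_new = np.exp(loglam_new)
        marg_new = self._marg_buf
        self._k.marg_rows(loglam_new, lam_new, st["B"], self.ptr,
                          self.nvals, self.lgfact, self.all_rows,
                          self._win_scr, marg_new)
        dll = np.bincount(group, marg_new - st["marg"], minlength=ngroups)
        acc = np.log(rng.random(ngroups)) < dll + dprior
        rows = acc[group]
        if np.any(rows):
            st["loglam"][rows] = loglam_new[rows]
            st["lam"][rows] = lam_new[rows]
            st["marg"][rows] = marg_new[rows]
        return acc

    def update_omega(self, st, step, rng):
        prop = st["omega"] + step * rng.normal(size=self.R)
        dpr = -0.5 * (prop**2 - st["omega"]**2) / st["s2_om"]
        loglam_new = st["loglam"] + (prop - st["omega"])[self.sy_site]
        acc = self._accept_lam(st, loglam_new, self.sy_site, self.R, dpr, rng)
        st["omega"][acc] = prop[acc]
        return acc

    def update_alpha(self, st, step, rng):
        prop = st["alpha"] + step * rng.normal(size=self.nk)
        dpr = -0.5 * (prop**2 - st["alpha"]**2) / st["s2_al"]
        loglam_new = st["loglam"] + (prop - st["alpha"])[self.sy_node]
        acc = self._accept_lam(st, loglam_new, self.sy_node, self.nk, dpr, rng)
        st["alpha"][acc] = prop[acc]
        return acc

    def update_beta(self, st, step, rng):
        prop = st["beta"] + step * rng.normal(size=self.nk)
        dpr = -0.5 * (prop**2 - st["beta"]**2) / st["s2_be"]
        loglam_new = st["loglam"] + (prop - st["beta"])[self.sy_node] * self.sy_x
        acc = self._accept_lam(st, loglam_new, self.sy_node, self.nk, dpr, rng)
        st["beta"][acc] = prop[acc]
        return acc

    def update_eps(self, st, step, rng):
        prop = st["eps"] + step * rng.normal(size=self.S)
        dpr = -0.5 * (prop**2 - st["eps"]**2) / st["s2_ep"]
        loglam_new = st["loglam"] + (prop - st["eps"])
        acc = self._accept_lam(st, loglam_new, np.arange(self.S), self.S, dpr, rng)
        st["eps"][acc] = prop[acc]
        return acc

    def update_gamma(self, st, step, rng):
        prop = st["gamma"] + step * rng.normal(size=self.K)
        p_new = expit(prop[self.sy_year][:, None] + st["delta"])
        Lb_new, B_new = self._Lb_scr, self._B_scr
        self._k.binom_table(p_new, self.C, self.M, self.logcoef,
                            self.nvals, self.ptr, Lb_new, B_new)
        marg_new = self._marg_buf
        self._k.marg_rows(st["loglam"], st["lam"], B_new, self.ptr,
                          self.nvals, self.lgfact, self.all_rows,
                          self._win_scr, marg_new)
        dll = np.bincount(self.sy_year, marg_new - st["marg"], minlength=self.K)
        dpr = -0.5 * (prop**2 - st["gamma"]**2) / _GAMMA_PRIOR_VAR
        acc = np.log(rng.random(self.K)) < dll + dpr
        rows = acc[self.sy_year]
        if np.any(rows):
            st["gamma"][acc] = prop[acc]
            st["p"][rows] = p_new[rows]
            self._k.commit_rows(np.flatnonzero(rows).astype(np.int64),
                                Lb_new, B_new, self.ptr, st["Lb"], st["B"])
            st["marg"][rows] = marg_new[rows]
        return acc

    def update_delta(self, st, steps, rng, parity=None):
        literal = self.spec.delta_prior == "literal_uniform"
        acc_all = np.zeros((self.S, self.J), dtype=float)
        prop_all = np.zeros((self.S, self.J), dtype=float)
        for j in range(self.J):
            if parity is not None and self.J > 2 and j % 2 != parity:
                continue
            rows = self.rows_j[j]
            if len(rows) == 0:
                continue
            prop_all[rows, j] = 1.0
            cur = st["delta"][rows, j]
            prop = cur + steps[rows, j] * rng.normal(size=len(rows))
            if literal:
                dpr = np.where((prop >= 0) & (prop <= _DELTA_SD_BOUND), 0.0, -np.inf)
            else:
                dpr = -0.5 * (prop**2 - cur**2) / st["s2_de"]
            p_new = expit(st["gamma"][self.sy_year[rows]] + prop)
            Lbcol, B_new = self._Lbcol_scr, self._B_scr
            self._k.binom_col(p_new, rows, j, self.C, self.logcoef,
                              self.nvals, self.ptr, st["Lb"], st["B"],
                              Lbcol, B_new)
            marg_new = self._marg_buf[: len(rows)]
            self._k.marg_rows(st["loglam"], st["lam"], B_new, self.ptr,
                              self.nvals, self.lgfact, rows,
                              self._win_scr, marg_new)
            acc = np.log(rng.random(len(rows))) < marg_new - st["marg"][rows] + dpr
            hit = rows[acc]
            if len(hit):
                st["delta"][hit, j] = prop[acc]
                st["p"][hit, j] = p_new[acc]
                self._k.commit_col(hit, j, Lbcol, B_new, self.ptr,
                                   st["Lb"], st["B"])
                st["marg"][hit] = marg_new[acc]
            acc_all[rows, j] = acc
        return acc_all, prop_all

    # -- joint moves for weakly identified directions ---------------------
    # Level and trend can trade between the abundance and detection sides
    # (lambda * P is much better identified than either factor), and the
    # hierarchy lets random-effect means trade against fixed effects. The
    # recentering moves below are exact Gibbs draws along directions that
    # leave the likelihood invariant; the two ridge moves are joint
    # random-walk proposals along the lambda-P trade-off.

    def recenter(self, st, rng):
        def shifts(prec, mean_num, size):
            return mean_num / prec + rng.normal(size=size) / np.sqrt(prec)

        # alpha_k <-> omega_i (sites of node k)
        n_sites = np.bincount(self.site_node, minlength=self.nk)
        sum_om = np.bincount(self.site_node, st["omega"], minlength=self.nk)
        d = shifts(1 / st["s2_al"] + n_sites / st["s2_om"],
                   -st["alpha"] / st["s2_al"] + sum_om / st["s2_om"], self.nk)
        st["alpha"] += d
        st["omega"] -= d[self.site_node]
        # omega_i <-> eps_it
        n_rows = np.bincount(self.sy_site, minlength=self.R)
        sum_ep = np.bincount(self.sy_site, st["eps"], minlength=self.R)
        d = shifts(1 / st["s2_om"] + n_rows / st["s2_ep"],
                   -st["omega"] / st["s2_om"] + sum_ep / st["s2_ep"], self.R)
        st["omega"] += d
        st["eps"] -= d[self.sy_site]
        # beta_k <-> eps_it along the centred-year direction
        xx = np.bincount(self.sy_node, self.sy_x**2, minlength=self.nk)
        xe = np.bincount(self.sy_node, st["eps"] * self.sy_x, minlength=self.nk)
        d = shifts(1 / st["s2_be"] + xx / st["s2_ep"],
                   -st["beta"] / st["s2_be"] + xe / st["s2_ep"], self.nk)
        st["beta"] += d
        st["eps"] -= d[self.sy_node] * self.sy_x
        # gamma_t <-> delta_ijt
        if self.spec.delta_prior == "hierarchical":
            dmask = np.where(self.M, st["delta"], 0.0)
            n_de = np.bincount(self.sy_year, self.M.sum(axis=1), minlength=self.K)
            sum_de = np.bincount(self.sy_year, dmask.sum(axis=1), minlength=self.K)
            d = shifts(1 / _GAMMA_PRIOR_VAR + n_de / st["s2_de"],
                       -st["gamma"] / _GAMMA_PRIOR_VAR + sum_de / st["s2_de"],
                       self.K)
            st["gamma"] += d
            st["delta"] = np.where(
                self.M, st["delta"] - d[self.sy_year][:, None], st["delta"]
            )
        st["loglam"] = self._loglam(st)
        st["lam"] = np.exp(np.clip(st["loglam"], -30, 30))

    _RIDGE_KAPPA = 2.5  # ~ d logit(p) / d log(lambda) holding lambda*p, p~0.6

    def _ridge_accept(self, st, alpha_new, beta_new, gamma_new,
                      loglam_new, dprior, rng):
        loglam_new = np.clip(loglam_new, -30, 30)
        lam_new = np.exp(loglam_new)
        p_new = expit(gamma_new[self.sy_year][:, None] + st["delta"])
        Lb_new, B_new = self._Lb_scr, self._B_scr
        self._k.binom_table(p_new, self.C, self.M, self.logcoef,
                            self.nvals, self.ptr, Lb_new, B_new)
        marg_new = self._marg_buf
        self._k.marg_rows(loglam_new, lam_new, B_new, self.ptr,
                          self.nvals, self.lgfact, self.all_rows,
                          self._win_scr, marg_new)
        if np.log(rng.random()) < marg_new.sum() - st["marg"].sum() + dprior:
            st["alpha"] = alpha_new
            st["beta"] = beta_new
            st["gamma"] = gamma_new
            st["loglam"] = loglam_new.copy()
            st["lam"] = lam_new
            st["p"] = p_new
            st["Lb"], self._Lb_scr = Lb_new, st["Lb"]
            st["B"], self._B_scr = B_new, st["B"]
            st["marg"], self._marg_buf = marg_new, st["marg"]
            return True
        return False

    def ridge_level(self, st, step, rng):
        """All intercepts up / yearly detection levels down jointly,
        approximately preserving lambda*P."""
        d = step * rng.normal()
        alpha_new = st["alpha"] + d
        gamma_new = st["gamma"] - self._RIDGE_KAPPA * d
        dpr = (-0.5 * ((alpha_new**2 - st["alpha"]**2).sum()) / st["s2_al"]
               - 0.5 * ((gamma_new**2 - st["gamma"]**2).sum()) / _GAMMA_PRIOR_VAR)
        return self._ridge_accept(st, alpha_new, st["beta"], gamma_new,
                                  st["loglam"] + d, dpr, rng)

    def ridge_trend(self, st, step, rng):
        """Trends up / detection time-trend down along the centred year."""
        d = step * rng.normal()
        beta_new = st["beta"] + d
        gamma_new = st["gamma"] - self._RIDGE_KAPPA * d * self.x_year
        dpr = (-0.5 * ((beta_new**2 - st["beta"]**2).sum()) / st["s2_be"]
               - 0.5 * ((gamma_new**2 - st["gamma"]**2).sum()) / _GAMMA_PRIOR_VAR)
        return self._ridge_accept(st, st["alpha"], beta_new, gamma_new,
                                  st["loglam"] + d * self.sy_x, dpr, rng)

    def scale_move_lam(self, st, which, step, rng):
        """Interweaving move: rescale a log-abundance random-effect vector
        and its variance jointly (multiplicative walk on the hierarchy's
        scale), which decouples the variance from its effects."""
        r = float(np.exp(step * rng.normal()))
        if which == "omega":
            vec, s2key, n = st["omega"], "s2_om", self.R
            add = ((r - 1.0) * vec)[self.sy_site]
        else:
            vec, s2key, n = st["eps"], "s2_ep", self.S
            add = (r - 1.0) * vec
        loglam_new = np.clip(st["loglam"] + add, -30, 30)
        lam_new = np.exp(loglam_new)
        marg_new = self._marg_buf
        self._k.marg_rows(loglam_new, lam_new, st["B"], self.ptr,
                          self.nvals, self.lgfact, self.all_rows,
                          self._win_scr, marg_new)
        s2 = st[s2key]
        logr = np.log(r)
        dpr = (-2 * _IG_SHAPE * logr
               - _IG_SCALE * (1.0 / (r * r * s2) - 1.0 / s2))
        if np.log(rng.random()) < marg_new.sum() - st["marg"].sum() + dpr:
            vec *= r
            st[s2key] = s2 * r * r
            st["loglam"] = loglam_new.copy()
            st["lam"] = lam_new
            st["marg"], self._marg_buf = marg_new, st["marg"]
            return True
        return False

    def scale_move_delta(self, st, step, rng):
        """Joint rescale of replicate detection effects and their variance."""
        if self.spec.delta_prior != "hierarchical":
            return False
        r = float(np.exp(step * rng.normal()))
        s2_new = st["s2_de"] * r * r
        if np.sqrt(s2_new) >= _DELTA_SD_BOUND:
            return False
        delta_new = np.where(self.M, st["delta"] * r, st["delta"])
        p_new = expit(st["gamma"][self.sy_year][:, None] + delta_new)
        Lb_new, B_new = self._Lb_scr, self._B_scr
        self._k.binom_table(p_new, self.C, self.M, self.logcoef,
                            self.nvals, self.ptr, Lb_new, B_new)
        marg_new = self._marg_buf
        self._k.marg_rows(st["loglam"], st["lam"], B_new, self.ptr,
                          self.nvals, self.lgfact, self.all_rows,
                          self._win_scr, marg_new)
        # uniform prior on the sd plus the map's Jacobian leave +log r
        if np.log(rng.random()) < (marg_new.sum() - st["marg"].sum()
                                   + np.log(r)):
            st["delta"] = delta_new
            st["s2_de"] = s2_new
            st["p"] = p_new
            st["Lb"], self._Lb_scr = Lb_new, st["Lb"]
            st["B"], self._B_scr = B_new, st["B"]
            st["marg"], self._marg_buf = marg_new, st["marg"]
            return True
        return False

    def update_variances(self, st, rng):
        def ig(shape, scale):
            return float(scale / rng.gamma(shape))

        st["s2_om"] = ig(_IG_SHAPE + self.R / 2,
                         _IG_SCALE + float(st["omega"] @ st["omega"]) / 2)
        st["s2_ep"] = ig(_IG_SHAPE + self.S / 2,
                         _IG_SCALE + float(st["eps"] @ st["eps"]) / 2)
        if self.spec.delta_prior == "hierarchical":
            d = st["delta"][self.M]
            n = d.size
            # sigma_delta ~ Uniform(0, 100): conditional of the variance is
            # inverse-gamma((n-1)/2, sum d^2/2) truncated at the bound
            for _ in range(20):
                s2 = ig((n - 1) / 2, float(d @ d) / 2 + 1e-12)
                if np.sqrt(s2) < _DELTA_SD_BOUND:
                    st["s2_de"] = s2
                    break

    def sample_latent_N(self, st, rng):
        u = rng.random(self.S)
        self._k.sample_latent(st["loglam"], st["lam"], st["B"], self.ptr,
                              self.nvals, self.lgfact, u, self._win_scr,
                              self._Nout)
        return self._Nout.astype(np.int64)


def _prepare(data: CountDataset, spec: NmixtureSpec):
    arrays = data.to_arrays()
    if len(arrays["years"]) < 2:
        raise ValueError("need counts from at least 2 years")
    if spec.variant == "node":
        if len(arrays["sites"]) < 2:
            raise ValueError("node model needs at least 2 sites")
        sy_node = arrays["site_node"][arrays["sy_site"]]
        for k, node in enumerate(arrays["nodes"]):
            if (sy_node == k).sum() < 2:
                raise ValueError(
                    f"node {node!r} has a single site-year; "
                    "too few data for a node-level trend"
                )
        n_nodes = len(arrays["nodes"])
    else:
        if len(arrays["sites"]) == 1:
            warnings.warn(
                "single-site dataset: site random-effect variance is weakly "
                "identified"
            )
            logger.warning("fitting flyway model to a single site")
        arrays = dict(arrays)
        arrays["site_node"] = np.zeros(len(arrays["sites"]), dtype=int)
        n_nodes = 1
    return arrays, n_nodes


_ADAPT_BATCH = 50
_TARGET_ACC = 0.44


def _fit(data: CountDataset, spec: NmixtureSpec) -> NmixturePosterior:
    spec.validate()
    arrays, n_nodes = _prepare(data, spec)
    smp = _NmixSampler(arrays, spec, n_nodes)
    n_keep = spec.draws // spec.thin
    store = {
        "alpha": np.empty((spec.chains, n_keep, n_nodes)),
        "beta": np.empty((spec.chains, n_keep, n_nodes)),
        "gamma": np.empty((spec.chains, n_keep, smp.K)),
        "omega": np.empty((spec.chains, n_keep, smp.R), dtype=np.float32),
        "eps": np.empty((spec.chains, n_keep, smp.S), dtype=np.float32),
        "loglam": np.empty((spec.chains, n_keep, smp.S), dtype=np.float32),
        "p": np.empty((spec.chains, n_keep, smp.S, smp.J), dtype=np.float32),
        "N": np.empty((spec.chains, n_keep, smp.S), dtype=np.int32),
        "sigma_omega": np.empty((spec.chains, n_keep)),
        "sigma_eps": np.empty((spec.chains, n_keep)),
        "sigma_delta": np.empty((spec.chains, n_keep)),
        "lp": np.empty((spec.chains, n_keep)),
    }

    ss = np.random.SeedSequence(spec.seed)
    for chain, child in enumerate(ss.spawn(spec.chains)):
        rng = np.random.default_rng(child)
        st = smp.init_state(rng)
        steps = {
            "omega": np.full(smp.R, 0.12),
            "alpha": np.full(smp.nk, 0.06),
            "beta": np.full(smp.nk, 0.01),
            "eps": np.full(smp.S, 0.15),
            "gamma": np.full(smp.K, 0.12),
            "delta": np.full((smp.S, smp.J), 0.3),
            "ridge_level": np.array(0.1),
            "ridge_trend": np.array(0.01),
        }
        steps.update({
            "scale_omega": np.array(0.15),
            "scale_eps": np.array(0.15),
            "scale_delta": np.array(0.15),
        })
        acc_ct = {k: np.zeros_like(v, dtype=float) for k, v in steps.items()}
        prop_ct = {k: np.zeros_like(v, dtype=float) for k, v in steps.items()}

        def bump(key, acc, prop=1.0):
            acc_ct[key] += acc
            prop_ct[key] += prop

        nbatch = 0
        kept = 0
        for it in range(spec.warmup + spec.draws):
            bump("omega", smp.update_omega(st, steps["omega"], rng))
            bump("alpha", smp.update_alpha(st, steps["alpha"], rng))
            bump("beta", smp.update_beta(st, steps["beta"], rng))
            bump("eps", smp.update_eps(st, steps["eps"], rng))
            bump("gamma", smp.update_gamma(st, steps["gamma"], rng))
            dacc, dprop = smp.update_delta(st, steps["delta"], rng,
                                           parity=it % 2)
            bump("delta", dacc, dprop)
            smp.recenter(st, rng)
            if it % 2 == 0:
                bump("ridge_level",
                     smp.ridge_level(st, steps["ridge_level"], rng))
                bump("scale_eps",
                     smp.scale_move_lam(st, "eps", steps["scale_eps"], rng))
            else:
                bump("ridge_trend",
                     smp.ridge_trend(st, steps["ridge_trend"], rng))
                bump("scale_omega",
                     smp.scale_move_lam(st, "omega", steps["scale_omega"], rng))
            bump("scale_delta",
                 smp.scale_move_delta(st, steps["scale_delta"], rng))
            smp.update_variances(st, rng)

            if it < spec.warmup and (it + 1) % _ADAPT_BATCH == 0:
                nbatch += 1
                gain = min(0.25, 2.0 / np.sqrt(nbatch))
                for k in steps:
                    target = _TARGET_ACC
                    prop = np.maximum(prop_ct[k], 1.0)
                    rate = acc_ct[k] / prop
                    adj = np.where(prop_ct[k] > 0,
                                   np.exp(gain * (rate - target)), 1.0)
                    steps[k] = steps[k] * adj
                    acc_ct[k] = np.zeros_like(acc_ct[k])
                    prop_ct[k] = np.zeros_like(prop_ct[k])

            if it >= spec.warmup and (it - spec.warmup) % spec.thin == 0 \
                    and kept < n_keep:
                store["alpha"][chain, kept] = st["alpha"]
                store["beta"][chain, kept] = st["beta"]
                store["gamma"][chain, kept] = st["gamma"]
                store["omega"][chain, kept] = st["omega"]
                store["eps"][chain, kept] = st["eps"]
                store["loglam"][chain, kept] = st["loglam"]
                store["p"][chain, kept] = st["p"]
                store["N"][chain, kept] = smp.sample_latent_N(st, rng)
                store["sigma_omega"][chain, kept] = np.sqrt(st["s2_om"])
                store["sigma_eps"][chain, kept] = np.sqrt(st["s2_ep"])
                store["sigma_delta"][chain, kept] = np.sqrt(st["s2_de"])
                store["lp"][chain, kept] = st["marg"].sum()
                kept += 1

    diagnostics = _rhat_table(store, arrays, spec, n_nodes)
    converged = bool((diagnostics < spec.rhat_threshold).all())
    if not converged:
        bad = diagnostics[diagnostics >= spec.rhat_threshold]
        warnings.warn(
            f"non-converged MCMC: R-hat >= {spec.rhat_threshold} for "
            f"{bad.index.tolist()}"
        )
    variant = spec.variant
    return NmixturePosterior(
        draws=store, arrays=arrays, spec=spec, variant=variant,
        diagnostics=diagnostics, converged=converged,
    )


def _rhat_table(store, arrays, spec, n_nodes) -> pd.Series:
    labels = arrays["nodes"] if spec.variant == "node" else ["flyway"]
    vals = {}
    for k, lab in enumerate(labels):
        vals[f"alpha[{lab}]"] = store["alpha"][:, :, k]
        vals[f"beta[{lab}]"] = store["beta"][:, :, k]
    for t, y in enumerate(arrays["years"]):
        vals[f"gamma[{int(y)}]"] = store["gamma"][:, :, t]
    for name in ("sigma_omega", "sigma_eps", "sigma_delta"):
        vals[name] = store[name]
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lab, arr in vals.items():
            out[lab] = float(az.rhat(az.convert_to_dataset(np.asarray(arr)))["x"])
    return pd.Series(out)


def fit_node_model(data: CountDataset, spec: NmixtureSpec | None = None
                   ) -> NmixturePosterior:
    """Fit the node-level variant: intercept and trend per non-breeding node."""
    spec = spec or NmixtureSpec(variant="node")
    if spec.variant != "node":
        raise ValueError("spec.variant must be 'node'")
    return _fit(data, spec)


def fit_flyway_model(data: CountDataset, spec: NmixtureSpec | None = None
                     ) -> NmixturePosterior:
    """Fit the flyway variant: one intercept and one trend across all sites."""
    spec = spec or NmixtureSpec(variant="flyway")
    if spec.variant != "flyway":
        raise ValueError("spec.variant must be 'flyway'")
    return _fit(data, spec)


# ---------------------------------------------------------------------------
# posterior-based diagnostics and derived quantities
# ---------------------------------------------------------------------------

def posterior_predictive_check(post: NmixturePosterior, data: CountDataset,
                               seed: int = 0, eps: float = 0.5,
                               rng=None) -> float:
    """Bayesian p-value of a chi-square discrepancy.

    For each retained draw, computes sum_(i,j,t) (c - N P)^2 / (N P + eps)
    for the observed counts and for replicate counts simulated from the same
    draw (c_rep ~ Binomial(N, P)); returns the proportion of draws where the
    observed discrepancy exceeds the replicate one (ties split evenly).
    A value near 0.5 indicates adequate fit.
    """
    for key in ("N", "p"):
        if key not in post.draws:
            raise ValueError("posterior lacks retained latent draws")
    arrays = post.arrays
    C = arrays["C"]
    Mk = arrays["M"]
    N = post.draws["N"].reshape(-1, C.shape[0]).astype(np.int64)
    P = post.draws["p"].reshape(-1, C.shape[0], C.shape[1]).astype(float)
    rng = np.random.default_rng(seed) if rng is None else rng
    E = N[:, :, None] * P
    d_obs = ((C[None] - E) ** 2 / (E + eps))[:, Mk].sum(axis=1)
    c_rep = rng.binomial(np.broadcast_to(N[:, :, None], P.shape), P)
    d_rep = ((c_rep - E) ** 2 / (E + eps))[:, Mk].sum(axis=1)
    return float(np.mean(d_obs > d_rep) + 0.5 * np.mean(d_obs == d_rep))


def node_trend_odds_ratios(post: NmixturePosterior, level: float = 0.95
                           ) -> pd.DataFrame:
    """Pairwise odds ratios exp(beta_a) / exp(beta_b) between node trends.

    Returns the posterior mean and CRI of each pairwise ratio plus the mean
    absolute deviation of the ratio from 1 in percent — small values mean
    trends barely differ among nodes.
    """
    b = post.beta_draws()
    if b.shape[1] < 2:
        raise ValueError("pairwise odds ratios need a node-variant posterior "
                         "with >= 2 nodes")
    labels = post.node_labels
    a = (1 - level) / 2
    rows = []
    for i in range(len(labels)):
        for j in range(len(labels)):
            if i == j:
                continue
            ratio = np.exp(b[:, i] - b[:, j])
            rows.append({
                "node_a": labels[i], "node_b": labels[j],
                "mean": ratio.mean(),
                "lo": np.quantile(ratio, a), "hi": np.quantile(ratio, 1 - a),
                "mean_abs_dev_pct": 100.0 * np.abs(ratio - 1).mean(),
            })
    return pd.DataFrame(rows)


def derive_total_abundance(post: NmixturePosterior, level: float = 0.95,
                           include_unobserved: bool = True, seed: int = 0
                           ) -> pd.DataFrame:
    """Annual total abundance: per-year sums of latent N over sites.

    Observed site-years use the retained conditional N draws. For site-years
    with no counts (a site not surveyed in some year), latent abundance is
    imputed per draw from the model (fresh dispersion noise, Poisson draw)
    when ``include_unobserved`` — so totals refer to the same set of sites
    every year.
    """
    arrays = post.arrays
    S = arrays["C"].shape[0]
    N = post.draws["N"].reshape(-1, S).astype(np.int64)
    n_draws = N.shape[0]
    K = len(arrays["years"])
    R = len(arrays["sites"])
    totals = np.zeros((n_draws, K))
    np.add.at(totals.T, arrays["sy_year"], N.T)

    observed = np.zeros((R, K), dtype=bool)
    observed[arrays["sy_site"], arrays["sy_year"]] = True
    miss_site, miss_year = np.nonzero(~observed)
    if include_unobserved and len(miss_site):
        rng = np.random.default_rng(seed)
        omega = post.draws["omega"].reshape(n_draws, R).astype(float)
        alpha = post.draws["alpha"].reshape(n_draws, -1)
        beta = post.draws["beta"].reshape(n_draws, -1)
        sig_e = post.draws["sigma_eps"].reshape(n_draws)
        node_of = arrays["site_node"][miss_site]
        x = arrays["x_year"][miss_year]
        loglam = (omega[:, miss_site] + alpha[:, node_of]
                  + beta[:, node_of] * x[None, :]
                  + rng.normal(size=(n_draws, len(miss_site))) * sig_e[:, None])
        lam = np.exp(np.clip(loglam, -30, 25))
        Nmiss = rng.poisson(lam)
        np.add.at(totals.T, miss_year, Nmiss.T)

    a = (1 - level) / 2
    return pd.DataFrame({
        "year": arrays["years"],
        "mean": totals.mean(axis=0),
        "lo": np.quantile(totals, a, axis=0),
        "hi": np.quantile(totals, 1 - a, axis=0),
    })
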