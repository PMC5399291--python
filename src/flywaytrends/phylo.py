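"""Phylogenetic comparative regression with Bayesian variable selection.

Residuals of the taxon-level trend regression carry Brownian-motion
covariance: trait variance equals root-to-tip branch length, covariance the
depth of the most recent common ancestor. Tree uncertainty enters through a
set of R trees whose scaled inverse VCVs form the array Omega; one tree index
is drawn uniformly per MCMC iteration. Covariate importance is measured by
binary indicator variables v_c ~ Bernoulli(1/2) multiplying regression
coefficients theta_c (Kuo–Mallick selection); an indicator's posterior mean
near 1 marks an important predictor.

Intercept, coefficients and indicators are conjugate Gibbs draws (the
indicator draw integrates its coefficient out analytically); the two
variance parameters use log-scale random-walk Metropolis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import arviz as az
import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .datasets import ComparativeDataset, TreeSet


class ConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# VCV construction
# ---------------------------------------------------------------------------

def vcv_from_tree(tree: dendropy.Tree, taxon_order: Sequence[str] | None = None
                  ) -> np.ndarray:
    """Brownian-motion variance–covariance matrix of a rooted tree.

    Diagonal entries are root-to-tip distances; entry (a, b) is the depth of
    the most recent common ancestor of tips a and b. Rows/columns follow
    ``taxon_order`` (default: sorted tip labels).
    """
    if not tree.is_rooted:
        raise ValueError("tree must be rooted to define a Brownian VCV")
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    order = list(taxon_order) if taxon_order is not None else labels
    if sorted(order) != labels:
        raise ValueError(
            f"taxon_order {sorted(order)} does not match tree tips {labels}"
        )
    ix = {lab: i for i, lab in enumerate(order)}
    M = len(order)
    V = np.zeros((M, M))

    depth: dict = {}
    for nd in tree.preorder_node_iter():
        el = nd.edge.length
        if el is None:
            el = 0.0
        if el < 0:
            raise ValueError(
                f"negative branch length {el} above node {nd}"
            )
        parent = nd.parent_node
        depth[nd] = (depth[parent] if parent is not None else 0.0) + el

    tips_below: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            i = ix[nd.taxon.label]
            V[i, i] = depth[nd]
            tips_below[nd] = [i]
        else:
            groups = [tips_below[ch] for ch in nd.child_nodes()]
            d = depth[nd]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            V[a, b] = V[b, a] = d
            tips_below[nd] = [t for g in groups for t in g]
    return V


def scale_vcv(vcv: np.ndarray) -> np.ndarray:
    """Divide by tree height so the (ultrametric) diagonal becomes 1."""
    d = np.diagonal(vcv)
    height = float(d.max())
    if height <= 0:
        raise ValueError("tree height must be positive")
    if d.max() - d.min() > 1e-6 * height:
        warnings.warn(
            "non-constant VCV diagonal (tree not ultrametric); "
            "scaling by maximum root-to-tip height"
        )
    return vcv / height


def scale_and_invert(vcv: np.ndarray, cond_limit: float = 1e10,
                     strict: bool = False):
    """Scale a Brownian VCV to unit height and invert it.

    Returns ``(scaled, inverse)``. With the scaled matrix acting as a
    correlation structure, the regression's sigma^2 is a residual variance.
    Raises on non-positive-definite input, naming the offending leading
    minor; warns (or raises when ``strict``) on near-singular input.
    """
    V = np.asarray(vcv, dtype=float)
    if V.ndim != 2 or V.shape[0] != V.shape[1]:
        raise ValueError(f"expected square matrix, got shape {V.shape}")
    if not np.allclose(V, V.T, atol=1e-10):
        raise ValueError("VCV must be symmetric")
    S = scale_vcv(V)
    try:
        c, low = cho_factor(S)
    except np.linalg.LinAlgError:
        for k in range(1, S.shape[0] + 1):
            if np.linalg.det(S[:k, :k]) <= 0:
                raise ValueError(
                    f"matrix not positive definite: leading minor {k} "
                    "is non-positive"
                ) from None
        raise
    cond = np.linalg.cond(S)
    if cond > cond_limit:
        msg = f"near-singular scaled VCV (condition number {cond:.3g})"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    inv = cho_solve((c, low), np.eye(S.shape[0]))
    inv = 0.5 * (inv + inv.T)
    return S, inv


@dataclass
class VCVArray:
    """Omega: stacked inverses of unit-height Brownian VCVs, one per tree."""

    omega: np.ndarray          # (M, M, R) inverses
    scaled: np.ndarray         # (M, M, R) scaled VCVs
    taxa: list[str]
    heights: np.ndarray        # (R,) original tree heights

    def __post_init__(self) -> None:
        M = len(self.taxa)
        if self.omega.shape[:2] != (M, M) or self.omega.shape != self.scaled.shape:
            raise ValueError("inconsistent VCV array shapes")
        R = self.omega.shape[2]
        for q in range(R):
            err = np.abs(self.scaled[:, :, q] @ self.omega[:, :, q] - np.eye(M)).max()
            if err > 1e-8:
                raise ValueError(
                    f"inverse reconstruction error {err:.2e} for tree {q}"
                )

    @property
    def n_trees(self) -> int:
        return int(self.omega.shape[2])


def build_vcv_array(tree_set: TreeSet, taxon_order: Sequence[str] | None = None
                    ) -> VCVArray:
    """Scaled-and-inverted Brownian VCVs for every tree in the set."""
    order = list(taxon_order) if taxon_order is not None else tree_set.tip_labels()
    M, R = len(order), tree_set.n_trees
    omega = np.empty((M, M, R))
    scaled = np.empty((M, M, R))
    heights = np.empty(R)
    for q, tree in enumerate(tree_set.trees):
        V = vcv_from_tree(tree, taxon_order=order)
        heights[q] = float(np.diagonal(V).max())
        S, inv = scale_and_invert(V)
        scaled[:, :, q] = S
        omega[:, :, q] = inv
    return VCVArray(omega=omega, scaled=scaled, taxa=order, heights=heights)


# ---------------------------------------------------------------------------
# Bayesian variable selection regression
# ---------------------------------------------------------------------------

@dataclass
class BVSConfig:
    """Sampler and prior settings for the selection regression.

    Priors: intercept and coefficients ~ Normal(0, 1e3); variances ~
    inverse-gamma(1e-3, 1e-3); indicators ~ Bernoulli(1/2). The diffuse
    coefficient prior, combined with the collapsed indicator draw, acts as
    a strong Occam penalty: a covariate is retained only when its Bayes
    factor overcomes the prior's spread, which is what makes the indicator
    means decisive rather than hovering near the Bernoulli prior.
    """

    chains: int = 3
    draws: int = 3000
    warmup: int = 1000
    thin: int = 1
    seed: int = 0
    standardize: bool = True
    include_eps: bool = True
    fix_indicators: dict | None = None
    measurement_error: bool = False
    prior_var_intercept: float = 1e3
    prior_var_coef: float = 1e3
    ig_shape: float = 1e-3
    ig_scale: float = 1e-3
    indicator_prior: float = 0.5
    rhat_threshold: float = 1.1

    @classmethod
    def paper_preset(cls, **kw) -> "BVSConfig":
        """3 chains x 120,000 iterations, 20,000 burn-in, thin 3."""
        return cls(chains=3, draws=100_000 // 3, warmup=20_000, thin=3, **kw)


@dataclass
class BVSPosterior:
    """Posterior draws of the selection regression.

    ``draws`` arrays are (chains, draws, ...). ``beta`` is the effective
    coefficient v_c * theta_c on the standardized scale.
    """

    draws: dict
    covariates: list[str]
    meta: dict
    config: BVSConfig

    @property
    def indicator_means(self) -> pd.Series:
        v = self.draws["v"].reshape(-1, len(self.covariates))
        return pd.Series(v.mean(axis=0), index=self.covariates)

    def classification(self) -> pd.Series:
        return self.indicator_means.map(classify_indicator)

    def coefficient_summary(self, level: float = 0.95) -> pd.DataFrame:
        """Marginal and conditional-on-inclusion summaries of the effective
        coefficients beta_c = v_c * theta_c. The ``slope*`` columns condition
        on v_c = 1 — the scale on which a selected predictor's effect is
        reported."""
        beta = self.draws["beta"].reshape(-1, len(self.covariates))
        v = self.draws["v"].reshape(-1, len(self.covariates))
        a = (1 - level) / 2
        out = pd.DataFrame(
            {
                "indicator_mean": self.indicator_means,
                "mean": beta.mean(axis=0),
                "sd": beta.std(axis=0),
                "lo": np.quantile(beta, a, axis=0),
                "hi": np.quantile(beta, 1 - a, axis=0),
            },
            index=self.covariates,
        )
        slope, slo, shi = [], [], []
        for c in range(len(self.covariates)):
            sel = v[:, c] > 0
            if sel.any():
                bc = beta[sel, c]
                slope.append(bc.mean())
                slo.append(np.quantile(bc, a))
                shi.append(np.quantile(bc, 1 - a))
            else:
                slope.append(np.nan)
                slo.append(np.nan)
                shi.append(np.nan)
        out["slope"] = slope
        out["slope_lo"] = slo
        out["slope_hi"] = shi
        out["classification"] = self.classification()
        return out

    def rhat(self) -> pd.Series:
        vals = {}
        for name in ("alpha", "sigma2"):
            vals[name] = float(az.rhat(az.convert_to_dataset(self.draws[name]))["x"])
        for c, cov in enumerate(self.covariates):
            vals[f"beta[{cov}]"] = float(
                az.rhat(az.convert_to_dataset(self.draws["beta"][:, :, c]))["x"]
            )
        return pd.Series(vals)

    @property
    def converged(self) -> bool:
        r = self.rhat()
        return bool(np.all(np.isfinite(r) & (r < self.config.rhat_threshold))
                    or np.all(r[np.isfinite(r)] < self.config.rhat_threshold))


def fit_bvs_regression(data: ComparativeDataset, omega: VCVArray,
                       cfg: BVSConfig | None = None) -> BVSPosterior:
    """MCMC for the indicator-selection regression over a tree set.

    Per iteration a tree index q is drawn uniformly and the likelihood is
    Td ~ MVN(alpha + X (v * theta), sigma^2 C_q + sigma_eps^2 I): the
    i.i.d. error term is integrated out analytically rather than sampled,
    which keeps the covariate signal visible to the indicator updates
    (a sampled per-taxon error vector would absorb it and freeze the
    indicators). Intercept, coefficients, indicators and coefficient-prior
    hyperparameters are conjugate Gibbs draws; the two variances use
    random-walk Metropolis on the log scale. Taxon order of ``omega`` must
    equal ``data.taxa`` exactly (no silent reordering).
    """
    cfg = cfg or BVSConfig()
    if list(omega.taxa) != list(data.taxa):
        raise ValueError(
            "taxon order mismatch between VCV array and data: "
            f"{omega.taxa} vs {data.taxa}"
        )
    names = list(data.covariates)
    C = len(names)
    M = data.n_taxa
    if M <= C:
        warnings.warn(
            f"{M} taxa for {C} candidate covariates: selection is weakly informed"
        )
    if cfg.standardize:
        y, X, meta = data.standardized()
    else:
        y, X = data.response(), data.covariate_matrix()
        meta = {"y_mean": 0.0, "y_sd": 1.0,
                "x_mean": np.zeros(C), "x_sd": np.ones(C)}
    meta = dict(meta)
    meta["standardized"] = cfg.standardize

    se2 = None
    if cfg.measurement_error:
        if not {"trend_lo", "trend_hi"}.issubset(data.df.columns):
            raise ValueError("measurement_error requires trend_lo/trend_hi columns")
        se = (data.df["trend_hi"] - data.df["trend_lo"]).to_numpy() / (2 * 1.96)
        se2 = (se / meta["y_sd"]) ** 2

    fix = dict(cfg.fix_indicators or {})
    unknown = set(fix) - set(names)
    if unknown:
        raise ValueError(f"fix_indicators names not in covariates: {sorted(unknown)}")

    R = omega.n_trees
    n_keep = cfg.draws // cfg.thin
    stores = {
        "alpha": np.empty((cfg.chains, n_keep)),
        "theta": np.empty((cfg.chains, n_keep, C)),
        "v": np.empty((cfg.chains, n_keep, C)),
        "beta": np.empty((cfg.chains, n_keep, C)),
        "sigma2": np.empty((cfg.chains, n_keep)),
        "sigma2_eps": np.empty((cfg.chains, n_keep)),
        "tree_index": np.empty((cfg.chains, n_keep), dtype=int),
    }

    eye = np.eye(M)

    def cov_matrix(q, s2, s2e):
        Sigma = s2 * omega.scaled[:, :, q]
        if cfg.include_eps:
            Sigma = Sigma + s2e * eye
        if se2 is not None:
            Sigma = Sigma + np.diag(se2)
        return Sigma

    def mvn_loglik(resid, Sigma):
        cF = cho_factor(Sigma)
        logdet = 2.0 * np.log(np.diagonal(cF[0])).sum()
        return -0.5 * (logdet + float(resid @ cho_solve(cF, resid)))

    def log_ig(s2):
        return (-(cfg.ig_shape + 1) * np.log(s2) - cfg.ig_scale / s2)

    ss = np.random.SeedSequence(cfg.seed)
    for chain, child in enumerate(ss.spawn(cfg.chains)):
        rng = np.random.default_rng(child)
        alpha = float(rng.normal(0, 0.5))
        theta = rng.normal(0, 0.5, size=C)
        v = np.array([fix.get(nm, 1) for nm in names], dtype=float)
        s2_theta = np.full(C, cfg.prior_var_coef)
        s2 = 1.0
        s2_eps = 0.25 if cfg.include_eps else 0.0
        kept = 0
        for it in range(cfg.warmup + cfg.draws):
            q = int(rng.integers(R))
            Sigma = cov_matrix(q, s2, s2_eps)
            P = np.linalg.inv(Sigma)

            # intercept
            r0 = y - X @ (v * theta)
            prec = P.sum() + 1.0 / cfg.prior_var_intercept
            mean = (np.ones(M) @ P @ r0) / prec
            alpha = float(rng.normal(mean, np.sqrt(1.0 / prec)))

            # indicators and coefficients, one covariate at a time; the
            # indicator draw integrates theta_c out under its Normal prior
            # (collapsed Gibbs; a rank-1 update of the precision), which
            # keeps inclusion flips well mixed
            for c in range(C):
                xc = X[:, c]
                e_wo = y - alpha - X @ (v * theta) + v[c] * theta[c] * xc
                if names[c] not in fix:
                    Px = P @ xc
                    xPx = float(xc @ Px)
                    denom = 1.0 + s2_theta[c] * xPx
                    ll1 = (-0.5 * (float(e_wo @ P @ e_wo)
                                   - s2_theta[c] * float(Px @ e_wo) ** 2 / denom)
                           - 0.5 * np.log(denom))
                    ll0 = -0.5 * float(e_wo @ P @ e_wo)
                    pri = cfg.indicator_prior
                    p1 = 1.0 / (1.0 + (1 - pri) / pri
                                * np.exp(np.clip(ll0 - ll1, -700, 700)))
                    v[c] = 1.0 if rng.random() < p1 else 0.0
                if v[c] > 0:
                    prec_t = float(xc @ P @ xc) + 1.0 / s2_theta[c]
                    mean_t = float(xc @ P @ e_wo) / prec_t
                    theta[c] = float(rng.normal(mean_t, np.sqrt(1.0 / prec_t)))
                else:
                    theta[c] = float(rng.normal(0.0, np.sqrt(s2_theta[c])))

            # variances: random-walk Metropolis on the log scale
            resid = y - alpha - X @ (v * theta)
            ll_cur = mvn_loglik(resid, cov_matrix(q, s2, s2_eps))
            prop = s2 * float(np.exp(0.5 * rng.normal()))
            ll_prop = mvn_loglik(resid, cov_matrix(q, prop, s2_eps))
            # +log(s2) terms: Jacobian of the log-scale walk
            if np.log(rng.random()) < (ll_prop + log_ig(prop) + np.log(prop)
                                       - ll_cur - log_ig(s2) - np.log(s2)):
                s2, ll_cur = prop, ll_prop
            if cfg.include_eps:
                prop = s2_eps * float(np.exp(0.5 * rng.normal()))
                ll_prop = mvn_loglik(resid, cov_matrix(q, s2, prop))
                if np.log(rng.random()) < (ll_prop + log_ig(prop) + np.log(prop)
                                           - ll_cur - log_ig(s2_eps)
                                           - np.log(s2_eps)):
                    s2_eps, ll_cur = prop, ll_prop

            if it >= cfg.warmup and (it - cfg.warmup) % cfg.thin == 0 and kept < n_keep:
                stores["alpha"][chain, kept] = alpha
                stores["theta"][chain, kept] = theta
                stores["v"][chain, kept] = v
                stores["beta"][chain, kept] = v * theta
                stores["sigma2"][chain, kept] = s2
                stores["sigma2_eps"][chain, kept] = s2_eps
                stores["tree_index"][chain, kept] = q
                kept += 1

    return BVSPosterior(draws=stores, covariates=names, meta=meta, config=cfg)


def classify_indicator(posterior_mean: float) -> str:
    """Threshold classification of an indicator's posterior mean:
    >= 0.75 important, <= 0.25 unimportant, otherwise inconclusive."""
    if not 0.0 <= posterior_mean <= 1.0:
        raise ValueError(f"indicator posterior mean {posterior_mean} outside [0, 1]")
    if posterior_mean >= 0.75:
        return "important"
    if posterior_mean <= 0.25:
        return "unimportant"
    return "inconclusive"


@dataclass
class TwoStageReport:
    stage1: BVSPosterior
    stage2: BVSPosterior
    stage1_classification: pd.Series
    retained: pd.DataFrame
    intercept_only: bool = False


def two_stage_selection(data: ComparativeDataset, omega: VCVArray,
                        cfg: BVSConfig | None = None) -> TwoStageReport:
    """Selection with refit: covariates classified unimportant in stage 1
    have their indicators fixed to 0 in stage 2, sharpening the retained
    predictors' coefficients."""
    cfg = cfg or BVSConfig()
    stage1 = fit_bvs_regression(data, omega, cfg)
    cls1 = stage1.classification()
    fix = dict(cfg.fix_indicators or {})
    for cov, label in cls1.items():
        if label == "unimportant":
            fix[cov] = 0
    intercept_only = all(fix.get(c, None) == 0 for c in stage1.covariates)
    if intercept_only:
        warnings.warn("all covariates unimportant in stage 1; "
                      "stage 2 is an intercept-only fit")
    from dataclasses import replace

    cfg2 = replace(cfg, fix_indicators=fix)
    stage2 = fit_bvs_regression(data, omega, cfg2)
    summ = stage2.coefficient_summary()
    retained = summ.loc[[c for c in stage2.covariates if fix.get(c, None) != 0]]
    return TwoStageReport(
        stage1=stage1,
        stage2=stage2,
        stage1_classification=cls1,
        retained=retained,
        intercept_only=intercept_only,
    )
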