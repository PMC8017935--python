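"""Bayesian phylogenetic mixed models (Metropolis-within-Gibbs).

Two model families:

* a Poisson log-link model of per-species cooperative gene counts,
  ``E[Y_i] = exp(x_i' beta + u_i + e_i)`` with a phylogenetic random
  effect ``u ~ N(0, s2_p C)`` (C the Brownian shared-path covariance,
  scaled to unit diagonal) and an additive latent residual ``e ~ N(0,
  s2_e I)`` acting as overdispersion;
* a Gaussian model of per-(species, host) relatedness with host,
  species (iid) and species (phylogenetic) variance components.

The sampler uses conjugate normal block updates for the location
effects, inverse-gamma updates for the variance components (the
one-dimensional inverse-Wishart), and univariate adaptive random-walk
Metropolis on each latent log-rate for the Poisson likelihood.
Parameter expansion is available (and is the default for the Gaussian
model's random effects) to improve mixing when a variance component is
small.

Defaults follow common practice for this model family: weak
inverse-Wishart variance priors (V = 1, nu = 0.002), a diffuse normal
prior on fixed effects (variance 1e10), and two chains whose agreement
is checked with the Gelman-Rubin potential scale-reduction factor.
Fixed-effect significance is summarized as pMCMC: twice the posterior
mass on the opposite side of zero from the estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CollinearityWarning,
    ConvergenceWarning,
    DataError,
    DiagnosticError,
    ParameterError,
)

PSRF_THRESHOLD = 1.1


@dataclass
class PriorSpec:
    """Priors of the mixed models.

    ``variance_V``/``variance_nu`` parameterize the inverse-Wishart
    prior on each variance component (one-dimensional, so equivalent to
    inverse-gamma(nu/2, nu V / 2)). With ``parameter_expanded`` the
    non-residual variance components instead get the expanded prior
    (V = 1, nu = 1) with a working scale parameter alpha ~ N(alpha_mean,
    alpha_variance); the residual always keeps the inverse-Wishart.
    Fixed effects are a priori N(0, fixed_effect_variance).
    """

    fixed_effect_variance: float = 1e10
    variance_V: float = 1.0
    variance_nu: float = 0.002
    parameter_expanded: bool = False
    px_variance_nu: float = 1.0
    alpha_mean: float = 0.0
    alpha_variance: float = 1000.0

    def __post_init__(self):
        if self.variance_nu <= 0 or self.px_variance_nu <= 0:
            raise ParameterError("degrees of belief nu must be > 0")
        if self.fixed_effect_variance <= 0 or self.variance_V <= 0 or self.alpha_variance <= 0:
            raise ParameterError("prior variances must be > 0")


@dataclass
class McmcSettings:
    """Chain bookkeeping. Desk-scale defaults; ``paper_scale`` gives the
    full-length settings (1e6 iterations, burn-in 5,000, thin 50)."""

    n_iterations: int = 50_000
    burn_in: int = 5_000
    thinning: int = 10
    n_chains: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ParameterError("burn_in must be < n_iterations")
        if self.thinning < 1:
            raise ParameterError("thinning must be >= 1")
        if self.n_chains < 1:
            raise ParameterError("n_chains must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thinning

    @classmethod
    def paper_scale(cls, seed: int = 0) -> "McmcSettings":
        return cls(n_iterations=1_000_000, burn_in=5_000, thinning=50, n_chains=2, seed=seed)


@dataclass
class PhyloFit:
    """Posterior draws and summaries of one mixed-model fit.

    ``draws`` maps parameter name -> array of shape (n_chains,
    n_retained). ``summary`` has one row per parameter: term, kind
    (fixed/variance), posterior mean, 95% equal-tailed credible
    interval, pMCMC (fixed effects only) and PSRF (when >= 2 chains).
    """

    model: str
    fixed_terms: list
    draws: dict
    summary: pd.DataFrame
    settings: McmcSettings
    meta: dict = field(default_factory=dict)

    def pooled(self, name: str) -> np.ndarray:
        return np.concatenate(self.draws[name])

    def coefficient(self, name: str) -> pd.Series:
        row = self.summary[self.summary["term"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]

    def vcov(self, names) -> np.ndarray:
        """Posterior covariance matrix of the named coefficients."""
        mat = np.column_stack([self.pooled(n) for n in names])
        return np.cov(mat, rowvar=False)

    def write_summary(self, path) -> None:
        self.summary.to_csv(path, sep="\t", index=False)

    def write_draws(self, path) -> None:
        cols = {}
        for name, arr in self.draws.items():
            cols[name] = np.concatenate(arr)
        chain = np.repeat(
            np.arange(len(next(iter(self.draws.values())))),
            self.settings.n_retained,
        )
        df = pd.DataFrame(cols)
        df.insert(0, "chain", chain)
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def pmcmc(draws: np.ndarray) -> float:
    """Sign-symmetric MCMC p-value of one coefficient.

    ``2 * min(P(draw < 0), P(draw > 0))`` capped at one. For a positive
    estimate this equals twice the posterior probability of being
    negative; the symmetric form also behaves correctly for negative
    estimates.
    """
    draws = np.asarray(draws).ravel()
    if draws.size < 100:
        raise DiagnosticError("pMCMC requires at least 100 retained draws")
    neg = np.mean(draws < 0)
    pos = np.mean(draws > 0)
    return min(1.0, 2.0 * min(neg, pos))


def gelman_rubin(chains) -> float:
    """Potential scale-reduction factor from >= 2 aligned chains.

    Classic (non-split) PSRF: with m chains of length n, within-chain
    variance W and between-chain variance B, the pooled posterior
    variance estimate is ``(n-1)/n W + B/n`` and PSRF is the square
    root of its ratio to W.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise DiagnosticError("PSRF requires at least two equal-length chains")
    m, n = chains.shape
    if n < 2:
        raise DiagnosticError("chains too short for PSRF")
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B_over_n = means.var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    var_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_hat / W))


def _invgamma_draw(rng, shape, scale):
    return scale / rng.gamma(shape)


def _check_design(X: pd.DataFrame):
    mat = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        warnings.warn(
            f"fixed-effect design is rank deficient (columns: {list(X.columns)}); "
            "the affected coefficients are not identified and their pMCMC will be "
            "near 1",
            CollinearityWarning,
            stacklevel=3,
        )
    return mat


def _summarize(model, fixed_terms, chain_draws, settings, meta):
    names = list(chain_draws[0].keys())
    draws = {
        name: np.stack([cd[name] for cd in chain_draws]) for name in names
    }
    rows = []
    for name in names:
        pooled = np.concatenate(draws[name])
        mean = float(pooled.mean())
        lo, hi = np.quantile(pooled, [0.025, 0.975])
        is_fixed = name in fixed_terms
        p = pmcmc(pooled) if is_fixed else np.nan
        psrf = gelman_rubin(draws[name]) if len(chain_draws) >= 2 else np.nan
        rows.append(
            (name, "fixed" if is_fixed else "variance", mean, float(lo), float(hi), p, psrf)
        )
    summary = pd.DataFrame(
        rows,
        columns=["term", "kind", "mean", "ci_lower", "ci_upper", "pmcmc", "psrf"],
    )
    fit = PhyloFit(
        model=model,
        fixed_terms=list(fixed_terms),
        draws=draws,
        summary=summary,
        settings=settings,
        meta=meta,
    )
    worst = summary["psrf"].max()
    if len(chain_draws) >= 2 and np.isfinite(worst) and worst > PSRF_THRESHOLD:
        bad = summary.loc[summary["psrf"] > PSRF_THRESHOLD, "term"].tolist()
        warnings.warn(
            f"PSRF > {PSRF_THRESHOLD} for {bad} (max {worst:.3f}); "
            "chains may not have converged",
            ConvergenceWarning,
            stacklevel=3,
        )
    return fit


def _chol_inverse(C):
    n = C.shape[0]
    jitter = 1e-10 * np.eye(n)
    try:
        L = np.linalg.cholesky(C + jitter)
    except np.linalg.LinAlgError as exc:
        raise DataError("phylogenetic covariance is not positive definite") from exc
    Linv = np.linalg.solve(L, np.eye(n))
    return Linv.T @ Linv


def _sample_mvn_from_precision(rng, precision, linear):
    """Draw from N(P^-1 b, P^-1) given precision P and linear term b."""
    L = np.linalg.cholesky(precision)
    mean = np.linalg.solve(precision, linear)
    z = rng.standard_normal(len(linear))
    return mean + np.linalg.solve(L.T, z)


# ---------------------------------------------------------------------------
# Poisson model
# ---------------------------------------------------------------------------

def fit_poisson_pmm(
    y,
    X: pd.DataFrame,
    C: np.ndarray,
    prior: PriorSpec = None,
    mcmc: McmcSettings = None,
    fix_variances: dict = None,
) -> PhyloFit:
    """Fit the Poisson phylogenetic mixed model of a count trait.

    Parameters
    ----------
    y : array of nonnegative integers, one per species.
    X : DataFrame of fixed-effect columns aligned to ``C`` rows; an
        intercept column is prepended automatically.
    C : species x species Brownian covariance (unit diagonal
        recommended; see :func:`gutkin.trees.covariance_for`).
    fix_variances : dict, optional
        Map with keys ``"phylo"``/``"resid"`` to pin a variance
        component instead of sampling it. Pinning both to exactly zero
        collapses the model to a plain Poisson GLM, sampled by adaptive
        random-walk Metropolis on the coefficients (the GLM limit used
        for validation against iteratively reweighted least squares).
    """
    prior = prior or PriorSpec()
    mcmc = mcmc or McmcSettings()
    y = np.asarray(y)
    if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer):
        y = y.astype(float)
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise DataError("Poisson response must be nonnegative integers")
        y = y.astype(int)
    n = len(y)
    X = X.copy()
    X.insert(0, "intercept", 1.0)
    if len(X) != n or C.shape != (n, n):
        raise DataError("y, X and C dimensions do not agree")
    Xm = _check_design(X)
    terms = list(X.columns)
    fix_variances = dict(fix_variances or {})
    glm_limit = (
        fix_variances.get("phylo", None) == 0.0
        and fix_variances.get("resid", None) == 0.0
    )
    include_u = fix_variances.get("phylo", None) != 0.0
    if fix_variances.get("resid", None) == 0.0 and not glm_limit:
        raise ParameterError(
            "resid variance can only be pinned to zero together with the "
            "phylogenetic variance (the GLM limit)"
        )
    Cinv = _chol_inverse(C) if include_u else None

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    chain_draws = []
    for chain, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        if glm_limit:
            chain_draws.append(_run_poisson_glm_chain(rng, y, Xm, terms, prior, mcmc))
        else:
            chain_draws.append(
                _run_poisson_chain(
                    rng, y, Xm, terms, Cinv, prior, mcmc, fix_variances, include_u
                )
            )
    meta = {"n": n, "fix_variances": fix_variances, "glm_limit": glm_limit}
    return _summarize("poisson", terms, chain_draws, mcmc, meta)


def _run_poisson_chain(rng, y, Xm, terms, Cinv, prior, mcmc, fix_variances, include_u):
    n, p = Xm.shape
    eta = np.log(y + 0.5)
    beta = np.linalg.lstsq(Xm, eta, rcond=None)[0] + 0.1 * rng.standard_normal(p)
    u = np.zeros(n)
    s2p = float(fix_variances.get("phylo", 0.5) or 0.5) if include_u else 0.0
    if "phylo" in fix_variances and include_u:
        s2p = float(fix_variances["phylo"])
    s2e = float(fix_variances.get("resid", 0.5))
    sample_s2p = include_u and "phylo" not in fix_variances
    sample_s2e = "resid" not in fix_variances
    nu, V = prior.variance_nu, prior.variance_V
    v0 = prior.fixed_effect_variance

    step = np.full(n, 0.5)
    accept = np.zeros(n)
    out = {t: np.empty(mcmc.n_retained) for t in terms}
    out["var_phylo"] = np.empty(mcmc.n_retained) if include_u else None
    out["var_resid"] = np.empty(mcmc.n_retained)
    if not include_u:
        out.pop("var_phylo")
    kept = 0
    if include_u:
        dim = p + n
        prior_prec = np.zeros((dim, dim))
        prior_prec[:p, :p] = np.eye(p) / v0
        W = np.concatenate([Xm, np.eye(n)], axis=1)
    for it in range(1, mcmc.n_iterations + 1):
        # 1. latent log-rates, one univariate RW Metropolis step each
        mu = Xm @ beta + u
        prop = eta + step * rng.standard_normal(n)
        log_ratio = (
            y * (prop - eta)
            - (np.exp(prop) - np.exp(eta))
            - ((prop - mu) ** 2 - (eta - mu) ** 2) / (2.0 * s2e)
        )
        acc = np.log(rng.random(n)) < log_ratio
        eta[acc] = prop[acc]
        accept += acc
        if it <= mcmc.burn_in and it % 50 == 0:
            rate = accept / 50.0
            step *= np.exp(0.5 * (rate - 0.44))
            np.clip(step, 1e-3, 10.0, out=step)
            accept[:] = 0.0

        # 2. joint conjugate update of (beta, u)
        if include_u:
            A = prior_prec.copy()
            A += (W.T @ W) / s2e
            A[p:, p:] += Cinv / s2p
            b = W.T @ eta / s2e
            theta = _sample_mvn_from_precision(rng, A, b)
            beta, u = theta[:p], theta[p:]
        else:
            A = (Xm.T @ Xm) / s2e + np.eye(p) / v0
            b = Xm.T @ eta / s2e
            beta = _sample_mvn_from_precision(rng, A, b)

        # 3. variance components (one-dimensional inverse-Wishart)
        if sample_s2p:
            s2p = _invgamma_draw(rng, (nu + n) / 2.0, (nu * V + u @ Cinv @ u) / 2.0)
        if sample_s2e:
            resid = eta - Xm @ beta - u
            s2e = _invgamma_draw(rng, (nu + n) / 2.0, (nu * V + resid @ resid) / 2.0)

        if it > mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
            for j, t in enumerate(terms):
                out[t][kept] = beta[j]
            if include_u:
                out["var_phylo"][kept] = s2p
            out["var_resid"][kept] = s2e
            kept += 1
    return out


def _run_poisson_glm_chain(rng, y, Xm, terms, prior, mcmc):
    """Degenerate sampler for the zero-variance (plain GLM) limit."""
    n, p = Xm.shape
    beta = np.linalg.lstsq(Xm, np.log(y + 0.5), rcond=None)[0]
    v0 = prior.fixed_effect_variance

    def logpost(b):
        eta = Xm @ b
        return float(y @ eta - np.exp(eta).sum() - (b @ b) / (2 * v0))

    lp = logpost(beta)
    step = np.full(p, 0.1)
    accept = np.zeros(p)
    out = {t: np.empty(mcmc.n_retained) for t in terms}
    kept = 0
    for it in range(1, mcmc.n_iterations + 1):
        for j in range(p):
            prop = beta.copy()
            prop[j] += step[j] * rng.standard_normal()
            lp_prop = logpost(prop)
            if np.log(rng.random()) < lp_prop - lp:
                beta, lp = prop, lp_prop
                accept[j] += 1
        if it <= mcmc.burn_in and it % 50 == 0:
            step *= np.exp(0.5 * (accept / 50.0 - 0.44))
            np.clip(step, 1e-5, 10.0, out=step)
            accept[:] = 0.0
        if it > mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
            for j, t in enumerate(terms):
                out[t][kept] = beta[j]
            kept += 1
    return out


# ---------------------------------------------------------------------------
# Gaussian model
# ---------------------------------------------------------------------------

def fit_gaussian_pmm(
    y,
    X: pd.DataFrame,
    species_codes,
    C: np.ndarray,
    host_codes=None,
    include_species_iid: bool = True,
    prior: PriorSpec = None,
    mcmc: McmcSettings = None,
    fix_variances: dict = None,
) -> PhyloFit:
    """Fit the Gaussian mixed model of within-host relatedness.

    ``species_codes`` (and optionally ``host_codes``) map each
    observation to a species row of ``C`` (and a host level). Variance
    is partitioned into host, species (iid), species (phylogenetic) and
    residual components; by default the three non-residual components
    get the parameter-expanded prior. ``fix_variances`` pins components
    ("host", "species", "phylo", "resid"); a component pinned to zero
    is removed from the model.
    """
    prior = prior or PriorSpec(parameter_expanded=True)
    mcmc = mcmc or McmcSettings()
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = X.copy()
    X.insert(0, "intercept", 1.0)
    if len(X) != n:
        raise DataError("y and X lengths differ")
    Xm = _check_design(X)
    terms = list(X.columns)
    species_codes = np.asarray(species_codes, dtype=int)
    S = C.shape[0]
    if species_codes.max() >= S:
        raise DataError("species code exceeds covariance dimension")
    fix_variances = dict(fix_variances or {})

    blocks = []  # (name, codes, n_levels, Kinv or None)
    if host_codes is not None and fix_variances.get("host", None) != 0.0:
        host_codes = np.asarray(host_codes, dtype=int)
        blocks.append(("host", host_codes, host_codes.max() + 1, None))
    if include_species_iid and fix_variances.get("species", None) != 0.0:
        blocks.append(("species", species_codes, S, None))
    if fix_variances.get("phylo", None) != 0.0:
        blocks.append(("phylo", species_codes, S, _chol_inverse(C)))

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    chain_draws = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        chain_draws.append(
            _run_gaussian_chain(rng, y, Xm, terms, blocks, prior, mcmc, fix_variances)
        )
    meta = {"n": n, "blocks": [b[0] for b in blocks], "fix_variances": fix_variances}
    return _summarize("gaussian", terms, chain_draws, mcmc, meta)


def _run_gaussian_chain(rng, y, Xm, terms, blocks, prior, mcmc, fix_variances):
    n, p = Xm.shape
    v0 = prior.fixed_effect_variance
    nu, V = prior.variance_nu, prior.variance_V
    px = prior.parameter_expanded

    beta = np.linalg.lstsq(Xm, y, rcond=None)[0] + 0.1 * rng.standard_normal(p)
    state = {}
    contrib = {}
    for name, codes, q, Kinv in blocks:
        state[name] = {
            "v": np.zeros(q),
            "alpha": 1.0,
            "s2": float(fix_variances.get(name, 0.1)),
            "fixed": name in fix_variances,
            "codes": codes,
            "q": q,
            "Kinv": Kinv,
            "counts": np.bincount(codes, minlength=q).astype(float),
        }
        contrib[name] = np.zeros(n)
    s2e = float(fix_variances.get("resid", 0.1))
    sample_s2e = "resid" not in fix_variances

    XtX = Xm.T @ Xm
    out = {t: np.empty(mcmc.n_retained) for t in terms}
    for name, *_ in blocks:
        out[f"var_{name}"] = np.empty(mcmc.n_retained)
    out["var_resid"] = np.empty(mcmc.n_retained)
    kept = 0

    for it in range(1, mcmc.n_iterations + 1):
        # beta | rest
        resid = y - sum(contrib.values()) if blocks else y.copy()
        A = XtX / s2e + np.eye(p) / v0
        b = Xm.T @ resid / s2e
        beta = _sample_mvn_from_precision(rng, A, b)
        fitted_fixed = Xm @ beta

        # random-effect blocks
        for name, codes, q, Kinv in blocks:
            st = state[name]
            px_b = px and not st["fixed"]  # pinned components stay unexpanded
            partial = y - fitted_fixed - sum(
                contrib[o] for o in contrib if o != name
            )
            alpha = st["alpha"] if px_b else 1.0
            rhs = np.bincount(codes, weights=partial, minlength=q) * alpha / s2e
            if Kinv is None:
                prec_diag = st["counts"] * alpha**2 / s2e + 1.0 / st["s2"]
                v = rhs / prec_diag + rng.standard_normal(q) / np.sqrt(prec_diag)
            else:
                A = np.diag(st["counts"] * alpha**2 / s2e) + Kinv / st["s2"]
                v = _sample_mvn_from_precision(rng, A, rhs)
            st["v"] = v
            if px_b:
                t_vec = v[codes]
                tt = t_vec @ t_vec
                var_a = 1.0 / (tt / s2e + 1.0 / prior.alpha_variance)
                mean_a = var_a * (
                    t_vec @ partial / s2e + prior.alpha_mean / prior.alpha_variance
                )
                st["alpha"] = mean_a + np.sqrt(var_a) * rng.standard_normal()
            if not st["fixed"]:
                nu_b = prior.px_variance_nu if px_b else nu
                quad = v @ Kinv @ v if Kinv is not None else v @ v
                st["s2"] = _invgamma_draw(
                    rng, (nu_b + q) / 2.0, (nu_b * V + quad) / 2.0
                )
            contrib[name] = (st["alpha"] if px_b else 1.0) * st["v"][codes]

        # residual variance
        if sample_s2e:
            resid = y - fitted_fixed - sum(contrib.values()) if blocks else y - fitted_fixed
            s2e = _invgamma_draw(rng, (nu + n) / 2.0, (nu * V + resid @ resid) / 2.0)

        if it > mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0:
            for j, t in enumerate(terms):
                out[t][kept] = beta[j]
            for name, *_ in blocks:
                st = state[name]
                eff = (st["alpha"] ** 2 if px and not st["fixed"] else 1.0) * st["s2"]
                out[f"var_{name}"][kept] = eff
            out["var_resid"][kept] = s2e
            kept += 1
    return out
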