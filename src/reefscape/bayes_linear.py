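"""Gibbs sampler for Gaussian linear mixed models with ridge priors.

Model
-----
    y = X beta + sum_g Z_g u_g + eps
    beta_p   ~ Normal(0, coef_sd^2)          (population-level coefficients)
    u_gj     ~ Normal(0, sigma_g^2)          (varying intercepts, factor g)
    sigma_g  ~ half-Student-t(nu, 0, sd_scale)
    eps      ~ Normal(0, sigma^2),  sigma ~ half-Student-t(nu, 0, sd_scale)

The sampler is a Gibbs sweep with two refinements that matter for small
grouping factors (two observers):

* each group variance is updated by a univariate slice sampler on its log
  with the intercepts *integrated out analytically*, which removes the
  funnel between a scale and its few effects;
* a translation move resamples the jointly flat direction between
  indicator-coded coefficients and each intercept batch from its exact
  Gaussian conditional.

The residual variance uses the conjugate inverse-gamma mixture form of
the half-t prior.  Fixed effects and intercepts are conjugate Gaussian
draws.  Multiple chains run from a spawned seed sequence; draws come back
stacked ``(chain, draw)`` ready for rank-normalized R-hat and ESS
diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GibbsResult", "sample_lmm"]


@dataclass
class GibbsResult:
    """Posterior draws, stacked (chain, draw, ...)."""

    beta: np.ndarray                    # (chain, draw, p)
    sigma: np.ndarray                   # (chain, draw)
    coef_names: list[str]
    group_sds: dict[str, np.ndarray] = field(default_factory=dict)   # (chain, draw)
    group_effects: dict[str, np.ndarray] = field(default_factory=dict)  # (chain, draw, k_g)

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def flat_beta(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    def to_inference_data(self):
        """Package draws as an arviz.InferenceData for diagnostics."""
        import arviz as az

        posterior = {f"b_{name}": self.beta[:, :, k] for k, name in enumerate(self.coef_names)}
        posterior["sigma"] = self.sigma
        for gname, sds in self.group_sds.items():
            posterior[f"sd_{gname}"] = sds
        return az.from_dict(posterior=posterior)


def _inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return rate / rng.gamma(shape)


def _slice_sample_1d(logf, x0: float, rng: np.random.Generator, w: float = 1.0,
                     max_steps: int = 50) -> float:
    """One update of a univariate slice sampler with stepping-out."""
    height = logf(x0) - rng.exponential()
    lo = x0 - w * rng.uniform()
    hi = lo + w
    steps = max_steps
    while steps and logf(lo) > height:
        lo -= w
        steps -= 1
    steps = max_steps
    while steps and logf(hi) > height:
        hi += w
        steps -= 1
    while True:
        x1 = rng.uniform(lo, hi)
        if logf(x1) > height:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def sample_lmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: dict[str, np.ndarray] | None = None,
    *,
    coef_names: list[str] | None = None,
    coef_sd: float = 10.0,
    sd_scale: float = 10.0,
    sd_df: float = 3.0,
    chains: int = 4,
    iterations: int = 3000,
    warmup: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    shift_cols: np.ndarray | None = None,
) -> GibbsResult:
    """Draw from the posterior of a Gaussian linear mixed model.

    Parameters
    ----------
    y, X
        Response vector (n,) and fixed-effects design matrix (n, p).
    groups
        Mapping of factor name -> integer level index per observation
        (values in 0..k_g-1); each factor contributes varying intercepts.
    coef_sd
        Prior standard deviation of the fixed-effect Normal(0, coef_sd) prior.
    sd_scale, sd_df
        Scale and df of the half-Student-t prior on every standard
        deviation (residual and group-level).
    iterations, warmup
        Gibbs sweeps per chain and how many initial sweeps to discard.
    shift_cols
        Column indices of X forming an indicator partition (exactly one of
        them is 1 on every row, e.g. cell-means coding).  When varying
        intercepts are present, the overall level is only weakly identified
        against them; a translation move resamples the flat direction
        (shifting these coefficients against each intercept batch) from its
        exact Gaussian conditional, which restores fast mixing.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.size != n:
        raise ValueError("y and X disagree on the number of observations")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in y or X")
    if warmup >= iterations:
        raise ValueError("warmup must be smaller than iterations")
    groups = groups or {}
    gnames = list(groups)
    gidx = {g: np.asarray(groups[g], dtype=int).ravel() for g in gnames}
    glev = {g: int(gidx[g].max()) + 1 for g in gnames}
    for g in gnames:
        if gidx[g].size != n or gidx[g].min() < 0:
            raise ValueError(f"bad group index array for {g!r}")
    if coef_names is None:
        coef_names = [f"x{k}" for k in range(p)]
    if shift_cols is not None:
        shift_cols = np.asarray(shift_cols, dtype=int)

    XtX = X.T @ X
    prior_prec = np.eye(p) / coef_sd**2
    # group-summed design rows: X' Z_g u_g = Xg_g' applied to u_g
    Xg = {
        g: np.vstack([X[gidx[g] == j].sum(axis=0) for j in range(glev[g])])
        for g in gnames
    }
    yg = {g: np.bincount(gidx[g], weights=y, minlength=glev[g]) for g in gnames}
    ng = {g: np.bincount(gidx[g], minlength=glev[g]).astype(float) for g in gnames}

    keep = iterations - warmup
    beta_out = np.empty((chains, keep, p))
    sigma_out = np.empty((chains, keep))
    gsd_out = {g: np.empty((chains, keep)) for g in gnames}
    geff_out = {g: np.empty((chains, keep, glev[g])) for g in gnames}

    base = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    chain_seeds = base.spawn(chains)

    # ridge initialisation shared by all chains; chains diverge through noise
    beta_init = np.linalg.solve(XtX + prior_prec, X.T @ y)
    resid0 = y - X @ beta_init
    sigma_init = float(np.std(resid0)) or 1.0

    nu = float(sd_df)
    for c, ss in enumerate(chain_seeds):
        rng = np.random.default_rng(ss)
        beta = beta_init.copy()
        sigma2 = sigma_init**2
        u = {g: np.zeros(glev[g]) for g in gnames}
        su2 = {g: sd_scale**2 for g in gnames}
        a_e = 1.0
        for it in range(iterations):
            # --- fixed effects
            target = y.copy()
            for g in gnames:
                target -= u[g][gidx[g]]
            prec = XtX / sigma2 + prior_prec
            rhs = X.T @ target / sigma2
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, rhs)
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(chol.T, z)
            # --- varying intercepts per factor: update the group variance
            # with the intercepts integrated out (kills the funnel between
            # u and its scale when a factor has few levels), then draw the
            # intercepts conjugately
            for g in gnames:
                resid_g = y - X @ beta
                for h in gnames:
                    if h != g:
                        resid_g = resid_g - u[h][gidx[h]]
                sum_resid = np.bincount(gidx[g], weights=resid_g, minlength=glev[g])
                nj = ng[g]
                s2 = sigma2

                def log_post(theta: float) -> float:
                    # marginal over u_g, half-t prior on sd written on
                    # theta = log sigma_g^2 (0.5*theta includes the Jacobian)
                    v = np.exp(theta)
                    denom = s2 + nj * v
                    marg = -0.5 * np.sum(np.log(denom)) + 0.5 * v * np.sum(
                        sum_resid**2 / (s2 * denom)
                    )
                    prior = 0.5 * theta - 0.5 * (nu + 1.0) * np.log1p(
                        v / (nu * sd_scale**2)
                    )
                    return marg + prior

                su2[g] = float(np.exp(_slice_sample_1d(
                    log_post, np.log(su2[g]), rng, w=2.0
                )))
                prec_u = nj / sigma2 + 1.0 / su2[g]
                mean_u = (sum_resid / sigma2) / prec_u
                u[g] = mean_u + rng.standard_normal(glev[g]) / np.sqrt(prec_u)
            # --- residual sd
            resid = y - X @ beta
            for g in gnames:
                resid = resid - u[g][gidx[g]]
            sigma2 = _inv_gamma(
                rng, (nu + n) / 2.0, nu / a_e + 0.5 * float(resid @ resid)
            )
            a_e = _inv_gamma(rng, (nu + 1) / 2.0, nu / sigma2 + 1.0 / sd_scale**2)
            # --- translation move: beta[shift] + delta, u_g - delta leaves the
            # likelihood invariant; delta's conditional is Gaussian in the priors
            if shift_cols is not None and len(shift_cols):
                for g in gnames:
                    prec_d = glev[g] / su2[g] + len(shift_cols) / coef_sd**2
                    mean_d = (
                        u[g].sum() / su2[g] - beta[shift_cols].sum() / coef_sd**2
                    ) / prec_d
                    delta = mean_d + rng.standard_normal() / np.sqrt(prec_d)
                    u[g] -= delta
                    beta[shift_cols] += delta
            if it >= warmup:
                k = it - warmup
                beta_out[c, k] = beta
                sigma_out[c, k] = np.sqrt(sigma2)
                for g in gnames:
                    gsd_out[g][c, k] = np.sqrt(su2[g])
                    geff_out[g][c, k] = u[g]

    return GibbsResult(beta_out, sigma_out, list(coef_names), gsd_out, geff_out)
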