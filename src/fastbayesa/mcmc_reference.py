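"""Reference single-site Gibbs samplers for BayesA and BayesB.

These are the comparators the EM algorithm is judged against: BayesA bases
predictions on posterior *means* of SNP effects under the same scaled-t
prior for which the EM finds a joint posterior *mode*; BayesB adds a point
mass at zero with prior zero-proportion ``pi_zero``.

Sampling scheme (one iteration):

1. fixed effects: single-site normal full conditionals (flat prior);
2. each SNP in turn:
   - BayesB only: the inclusion indicator is drawn from its conditional
     with the effect integrated out, i.e. from the marginal likelihood
     ratio of "no effect" vs "normal effect with the current variance
     sigma2_j" — a plain Gibbs step on (indicator, effect, variance) since
     the variance is retained for excluded SNPs;
   - included effects: beta_j | rest ~ N(r_j / c_j, sigma2_e / c_j) with
     c_j = w_j'w_j + sigma2_e / sigma2_j and r_j the right-hand side
     adjusted for all other effects; excluded effects are set to zero;
   - effect variance: scaled-inv-chi2(nu + 1, (nu S + beta_j^2)/(nu + 1))
     for included SNPs, the prior scaled-inv-chi2(nu, S) when excluded;
3. residual variance from its scaled-inv-chi2 full conditional, with the
   same prior df as the effects and prior scale matched to the supplied
   true residual variance.

The hot loop is compiled with numba; a fixed seed gives bitwise-identical
chains.  With ``pi_zero = 0`` the BayesB kernel follows the BayesA code
path exactly (no indicator draws), so the two samplers coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np

from .fastbayesa_em import BayesAPrior
from .genomic_data import GenotypeMatrix, ValidationError, VarianceComponents
from .relationship import design_matrix

__all__ = ["McmcOptions", "PosteriorSummary", "bayesa_gibbs", "bayesb_gibbs"]


@dataclass(frozen=True)
class McmcOptions:
    """Chain length, burn-in, seed and (for BayesB) prior zero-proportion."""

    n_iter: int = 10_000
    burn_in: int = 1_000
    seed: int = 0
    pi_zero: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValidationError("need 0 <= burn_in < n_iter")
        if not 0.0 <= self.pi_zero < 1.0:
            raise ValidationError("pi_zero must be in [0, 1)")
        if self.n_iter < self.burn_in + 100:
            raise ValidationError(
                "n_iter too small: need at least burn_in + 100 iterations"
            )


@dataclass
class PosteriorSummary:
    """Posterior means over kept samples."""

    mean_effects: np.ndarray
    mean_inclusion: np.ndarray
    mean_residual_variance: float
    samples_kept: int
    mean_fixed_effects: np.ndarray | None = None


@numba.njit(cache=False)
def _gibbs_kernel(
    y, X, W, nu, S, nu_e, S_e, pi_zero, use_indicator,
    n_iter, burn_in, seed, sigma2_e_start, sigma2_start,
):  # pragma: no cover - exercised through the wrappers
    np.random.seed(seed)
    n = y.shape[0]
    p = X.shape[1]
    m = W.shape[1]

    xx = np.empty(p)
    for k in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, k] * X[i, k]
        xx[k] = s
    ww = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += W[i, j] * W[i, j]
        ww[j] = s

    b = np.zeros(p)
    beta = np.zeros(m)
    delta = np.ones(m)
    sigma2 = np.full(m, sigma2_start)
    sigma2_e = sigma2_e_start
    e = y.copy()  # residual y - Xb - W beta (b, beta start at zero)

    sum_beta = np.zeros(m)
    sum_delta = np.zeros(m)
    sum_b = np.zeros(p)
    sum_s2e = 0.0
    kept = 0

    for it in range(n_iter):
        # --- fixed effects, single-site with flat prior
        for k in range(p):
            r = 0.0
            for i in range(n):
                r += X[i, k] * e[i]
            r += xx[k] * b[k]
            mean = r / xx[k]
            sd = np.sqrt(sigma2_e / xx[k])
            b_new = np.random.normal(mean, sd)
            diff = b[k] - b_new
            for i in range(n):
                e[i] += X[i, k] * diff
            b[k] = b_new

        # --- SNP effects, variances and (BayesB) indicators
        for j in range(m):
            if ww[j] <= 0.0:
                beta[j] = 0.0
                sigma2[j] = (nu * S) / np.random.chisquare(nu)
                continue
            r = 0.0
            for i in range(n):
                r += W[i, j] * e[i]
            r += ww[j] * beta[j]  # RHS adjusted for all effects but j

            include = True
            if use_indicator:
                # log marginal-likelihood ratio included vs excluded,
                # effect integrated over N(0, sigma2_j)
                v = sigma2_e + ww[j] * sigma2[j]
                log_lr = -0.5 * np.log(v / sigma2_e) + 0.5 * r * r * sigma2[j] / (
                    sigma2_e * v
                )
                # p(include) = (1-pi) LR / ((1-pi) LR + pi), computed stably
                log_odds = np.log(1.0 - pi_zero) - np.log(pi_zero) + log_lr
                if log_odds > 35.0:
                    prob = 1.0
                elif log_odds < -35.0:
                    prob = 0.0
                else:
                    prob = 1.0 / (1.0 + np.exp(-log_odds))
                include = np.random.random() < prob

            if include:
                c = ww[j] + sigma2_e / sigma2[j]
                mean = r / c
                sd = np.sqrt(sigma2_e / c)
                b_new = np.random.normal(mean, sd)
                delta[j] = 1.0
            else:
                b_new = 0.0
                delta[j] = 0.0
            diff = beta[j] - b_new
            if diff != 0.0:
                for i in range(n):
                    e[i] += W[i, j] * diff
            beta[j] = b_new

            if include:
                scale = (nu * S + beta[j] * beta[j]) / (nu + 1.0)
                sigma2[j] = (nu + 1.0) * scale / np.random.chisquare(nu + 1.0)
            else:
                sigma2[j] = (nu * S) / np.random.chisquare(nu)

        # --- residual variance
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma2_e = (nu_e * S_e + sse) / np.random.chisquare(nu_e + n)

        if it >= burn_in:
            kept += 1
            for j in range(m):
                sum_beta[j] += beta[j]
                sum_delta[j] += delta[j]
            for k in range(p):
                sum_b[k] += b[k]
            sum_s2e += sigma2_e

    return sum_beta / kept, sum_delta / kept, sum_b / kept, sum_s2e / kept, kept


def _run_gibbs(
    y, X, genotypes, prior, vc, opts, use_indicator, center=True
) -> PosteriorSummary:
    y = np.ascontiguousarray(np.asarray(y, dtype=float))
    X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=float)))
    W = np.ascontiguousarray(design_matrix(genotypes, center=center))
    if X.shape[0] != y.shape[0] or W.shape[0] != y.shape[0]:
        raise ValidationError("y, X and genotypes have inconsistent row counts")
    # Residual-variance prior: same df as effects, prior mean = true value.
    nu_e = prior.df
    S_e = (nu_e - 2.0) / nu_e * vc.residual_variance
    # Effect variances start at the prior mean.
    sigma2_start = prior.df * prior.scale / (prior.df - 2.0) if prior.df > 2 else prior.scale
    mean_beta, mean_delta, mean_b, mean_s2e, kept = _gibbs_kernel(
        y, X, W,
        prior.df, prior.scale, nu_e, S_e,
        opts.pi_zero, use_indicator,
        opts.n_iter, opts.burn_in, opts.seed,
        vc.residual_variance, sigma2_start,
    )
    return PosteriorSummary(
        mean_effects=mean_beta,
        mean_inclusion=mean_delta,
        mean_residual_variance=float(mean_s2e),
        samples_kept=int(kept),
        mean_fixed_effects=mean_b,
    )


def bayesa_gibbs(
    y: np.ndarray,
    X: np.ndarray,
    genotypes: GenotypeMatrix | np.ndarray,
    prior: BayesAPrior,
    vc: VarianceComponents,
    opts: McmcOptions,
    center: bool = True,
) -> PosteriorSummary:
    """Single-site Gibbs sampler for the BayesA model (posterior means)."""
    return _run_gibbs(y, X, genotypes, prior, vc, opts, use_indicator=False,
                      center=center)


def bayesb_gibbs(
    y: np.ndarray,
    X: np.ndarray,
    genotypes: GenotypeMatrix | np.ndarray,
    prior: BayesAPrior,
    vc: VarianceComponents,
    opts: McmcOptions,
    center: bool = True,
) -> PosteriorSummary:
    """Gibbs sampler for BayesB: BayesA plus a point mass at zero.

    With ``opts.pi_zero == 0`` the indicator step is skipped and the chain
    is identical to :func:`bayesa_gibbs`.
    """
    use_indicator = opts.pi_zero > 0.0
    return _run_gibbs(y, X, genotypes, prior, vc, opts,
                      use_indicator=use_indicator, center=center)
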