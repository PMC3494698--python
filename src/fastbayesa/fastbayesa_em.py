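"""EM algorithm for BayesA-like genomic prediction (fastBayesA).

BayesA gives every SNP effect its own variance with a scaled inverse
chi-square prior, so the marginal effect prior is a scaled t and small
effects are shrunk harder than large ones.  Instead of sampling the
posterior by MCMC, the EM here treats the per-SNP variances as missing
data:

* E-step: given current effects, replace each variance by the value whose
  reciprocal is the conditional posterior expectation of ``1/sigma2_j``,
  namely ``(nu S + beta_j^2) / (nu + 1)``.
* M-step: with those variances on the diagonal of D, jointly re-estimate
  all SNP effects as BLUP through the equivalent animal model (dimension n,
  not m) followed by back-solving.

Iterating converges to a joint posterior mode of the SNP effects under the
BayesA model.  Variances are initialized at the GBLUP common variance, so
the first iteration *is* GBLUP and accuracy can only improve from there.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .blup_engine import FitResult, animal_model_blup, backsolve_snp_effects
from .genomic_data import GenotypeMatrix, ValidationError, VarianceComponents
from .relationship import EffectVariances, design_matrix, gblup_marker_variance

__all__ = [
    "BayesAPrior",
    "EMOptions",
    "EMIteration",
    "EMTrace",
    "scale_from_genetic_variance",
    "e_step_variances",
    "log_joint_posterior",
    "residual_variance_update",
    "convergence_metric",
    "fastbayesa_fit",
]

logger = logging.getLogger("fastbayesa")

#: Degrees of freedom of the effect-variance prior: the customary
#: low-information choice in the genomic-selection literature; must exceed
#: 2 for the prior mean of the variance to exist.
DEFAULT_DF = 4.012

#: Guard in the convergence metric's denominator.
_CONV_EPS = 1e-30


@dataclass(frozen=True)
class BayesAPrior:
    """Scaled inverse chi-square prior on per-SNP effect variances."""

    df: float
    scale: float

    def __post_init__(self) -> None:
        if not self.df > 0:
            raise ValidationError("prior degrees of freedom must be > 0")
        if not self.scale > 0:
            raise ValidationError("prior scale must be > 0")


@dataclass
class EMIteration:
    iteration: int
    convergence: float
    log_posterior: float
    beta_norm: float
    residual_variance: float
    validation_accuracy: float | None = None


@dataclass
class EMTrace:
    """Per-iteration convergence log of one EM run."""

    records: list[EMIteration] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def log_posteriors(self) -> np.ndarray:
        return np.array([r.log_posterior for r in self.records])

    @property
    def validation_accuracies(self) -> list[float | None]:
        return [r.validation_accuracy for r in self.records]


@dataclass
class EMOptions:
    """Tunables of the EM loop.

    ``tol`` applies to the relative squared change of the effect vector;
    ``update_residual`` switches on the mean-square-error residual update,
    which trades a little extra computation for less dispersion bias.
    """

    tol: float = 1e-8
    max_iter: int = 100
    update_residual: bool = False
    center: bool = True

    def __post_init__(self) -> None:
        if not self.tol > 0:
            raise ValidationError("tol must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")


def scale_from_genetic_variance(
    prior_df: float, vc: VarianceComponents, freqs: np.ndarray
) -> float:
    """Prior scale S so the prior-mean effect variance equals the GBLUP one.

    The scaled inverse chi-square mean is ``nu S / (nu - 2)``; setting it to
    ``sigma2_g / sum_j 2 p_j (1 - p_j)`` gives
    ``S = (nu - 2)/nu * sigma2_g / sum_j 2 p_j (1 - p_j)``.
    """
    if not prior_df > 2:
        raise ValidationError(
            f"prior df {prior_df} <= 2: the prior mean of the effect variance "
            "is undefined, cannot match it to the GBLUP variance"
        )
    common = gblup_marker_variance(vc, freqs)
    return (prior_df - 2.0) / prior_df * common


def e_step_variances(beta: np.ndarray, prior: BayesAPrior) -> EffectVariances:
    """Conditional-expectation update of the per-SNP effect variances.

    Given ``beta_j``, the variance's conditional posterior is scaled inverse
    chi-square with df ``nu + 1`` and scale ``(nu S + beta_j^2)/(nu + 1)``.
    The value returned per SNP is exactly that scale — the number whose
    reciprocal is ``E[1/sigma2_j | beta_j] = (nu + 1)/(nu S + beta_j^2)``,
    which is what the M-step's penalty needs.
    """
    beta = np.asarray(beta, dtype=float)
    return EffectVariances((prior.df * prior.scale + beta**2) / (prior.df + 1.0))


def log_joint_posterior(
    beta: np.ndarray,
    b: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    genotypes: GenotypeMatrix | np.ndarray,
    prior: BayesAPrior,
    residual_variance: float,
    center: bool = True,
) -> float:
    """Marginalized EM objective (constant terms dropped).

    ``-||y - Xb - W beta||^2 / (2 sigma2_e)
    - (nu + 1)/2 * sum_j log(nu S + beta_j^2)``
    — the Gaussian data log-likelihood plus the scaled-t log prior of the
    effects with all beta-free constants omitted.  EM ascends this quantity
    when the residual variance is held fixed.
    """
    W = design_matrix(genotypes, center=center)
    resid = np.asarray(y, float) - np.atleast_2d(X) @ np.asarray(b, float) - W @ np.asarray(beta, float)
    quad = float(resid @ resid) / (2.0 * residual_variance)
    penalty = 0.5 * (prior.df + 1.0) * float(
        np.sum(np.log(prior.df * prior.scale + np.asarray(beta, float) ** 2))
    )
    return -quad - penalty


def residual_variance_update(
    y: np.ndarray,
    X: np.ndarray,
    b: np.ndarray,
    genotypes: GenotypeMatrix | np.ndarray,
    beta: np.ndarray,
    center: bool = True,
) -> float:
    """Mean-square-error update of the residual variance."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] == 0:
        raise ValidationError("cannot update residual variance with zero records")
    W = design_matrix(genotypes, center=center)
    resid = y - np.atleast_2d(X) @ np.asarray(b, float) - W @ np.asarray(beta, float)
    return float(resid @ resid) / y.shape[0]


def convergence_metric(beta_new: np.ndarray, beta_old: np.ndarray) -> float:
    """Relative squared change of the effect vector between iterations."""
    beta_new = np.asarray(beta_new, dtype=float)
    beta_old = np.asarray(beta_old, dtype=float)
    if beta_new.shape != beta_old.shape:
        raise ValidationError("effect vectors differ in length")
    num = float(np.sum((beta_new - beta_old) ** 2))
    den = max(float(np.sum(beta_old**2)), _CONV_EPS)
    return num / den


def fastbayesa_fit(
    y: np.ndarray,
    X: np.ndarray,
    genotypes: GenotypeMatrix | np.ndarray,
    vc: VarianceComponents,
    prior: BayesAPrior | None = None,
    options: EMOptions | None = None,
    validation: tuple[GenotypeMatrix | np.ndarray, np.ndarray] | None = None,
) -> FitResult:
    """Fit SNP effects to a joint posterior mode under the BayesA model.

    Parameters
    ----------
    y, X, genotypes
        Training phenotypes, fixed-effect design (full column rank; an
        intercept column in experiments) and training genotypes.  A plain
        ndarray is accepted in place of a :class:`GenotypeMatrix` and used
        as the ready design matrix.
    vc
        True (or externally estimated) variance components; the genetic
        variance fixes the GBLUP starting variance and the prior scale, the
        residual variance is used as-is unless ``options.update_residual``.
    prior
        Defaults to df 4.012 with scale matched to the GBLUP variance.
    validation
        Optional ``(genotypes, tbv)`` pair; when given, the trace records
        the first-validation-set GEBV accuracy at every iteration
        (iteration 1 equals GBLUP accuracy by construction).

    Returns a :class:`FitResult` whose ``trace`` is an :class:`EMTrace`.
    Non-convergence at ``max_iter`` warns and returns ``converged=False``.
    """
    options = options or EMOptions()
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))

    if isinstance(genotypes, GenotypeMatrix):
        freqs = genotypes.allele_freqs()
        sum2pq = float(np.sum(2.0 * freqs * (1.0 - freqs)))
        individuals = list(genotypes.individuals)
        locus_ids = genotypes.locus_ids
        m = genotypes.n_loci
    else:
        # Ready design matrix: per-column sample variance plays the role of
        # 2p(1-p) in mapping sigma2_g onto a common effect variance.
        Wraw = np.asarray(genotypes, dtype=float)
        sum2pq = float(np.sum(Wraw.var(axis=0))) if Wraw.size else 0.0
        freqs = None
        individuals = [str(i) for i in range(Wraw.shape[0])]
        locus_ids = [f"col{j}" for j in range(Wraw.shape[1])]
        m = Wraw.shape[1]

    if m == 0:
        # Fixed-effect-only degenerate fit, one iteration, converged.
        b_hat = np.linalg.lstsq(X, y, rcond=None)[0]
        return FitResult(
            fixed_effects=b_hat,
            snp_effects=np.zeros(0),
            gebv=np.zeros(y.shape[0]),
            effect_variances=EffectVariances(np.empty(0)),
            residual_variance=vc.residual_variance,
            individuals=individuals,
            locus_ids=locus_ids,
            centered=options.center,
            converged=True,
            n_iterations=1,
            prior=prior,
            trace=EMTrace(),
        )

    if sum2pq <= 0:
        raise ValidationError("all loci monomorphic: nothing to fit")
    gblup_var = vc.genetic_variance / sum2pq
    if prior is None:
        prior = BayesAPrior(
            df=DEFAULT_DF, scale=(DEFAULT_DF - 2.0) / DEFAULT_DF * gblup_var
        )
    variance_floor = 1e-12 * gblup_var  # numerical guard; keeps D invertible

    sigma2_e = vc.residual_variance
    D = EffectVariances.common(gblup_var, m)
    beta_old = np.zeros(m)
    trace = EMTrace()
    converged = False
    b_hat = np.zeros(X.shape[1])
    beta = beta_old
    g_hat = np.zeros(y.shape[0])
    n_done = 0

    for iteration in range(1, options.max_iter + 1):
        # M-step: joint BLUP of all SNP effects via the animal model.
        b_hat, g_hat, projected = animal_model_blup(
            y, X, genotypes, D, sigma2_e, center=options.center
        )
        beta = backsolve_snp_effects(genotypes, D, projected, center=options.center)
        n_done = iteration

        metric = convergence_metric(beta, beta_old)
        lp = log_joint_posterior(
            beta, b_hat, y, X, genotypes, prior, sigma2_e, center=options.center
        )
        acc = None
        if validation is not None:
            acc = _validation_accuracy(validation, beta, freqs, options.center)
        trace.records.append(
            EMIteration(
                iteration=iteration,
                convergence=metric,
                log_posterior=lp,
                beta_norm=float(np.linalg.norm(beta)),
                residual_variance=sigma2_e,
                validation_accuracy=acc,
            )
        )

        if options.update_residual:
            sigma2_e = residual_variance_update(
                y, X, b_hat, genotypes, beta, center=options.center
            )

        if iteration > 1 and metric < options.tol:
            converged = True
            break

        # E-step: conditional expectation of each SNP's effect variance.
        D = e_step_variances(beta, prior)
        D = EffectVariances(np.maximum(D.values, variance_floor))
        beta_old = beta

    if not converged:
        warnings.warn(
            f"fastBayesA did not reach tol={options.tol:g} within "
            f"{options.max_iter} iterations (last metric "
            f"{trace.records[-1].convergence:g})",
            RuntimeWarning,
            stacklevel=2,
        )

    return FitResult(
        fixed_effects=b_hat,
        snp_effects=beta,
        gebv=g_hat,
        effect_variances=D,
        residual_variance=sigma2_e,
        individuals=individuals,
        locus_ids=locus_ids,
        centered=options.center,
        centering_freqs=freqs if options.center else None,
        converged=converged,
        n_iterations=n_done,
        prior=prior,
        trace=trace,
    )


def _validation_accuracy(validation, beta, train_freqs, center) -> float | None:
    from .blup_engine import predict_gebv
    from .evaluation import UndefinedMetricError, accuracy

    G_val, tbv = validation
    gebv = predict_gebv(
        G_val, beta, centering_freqs=train_freqs if center else None
    )
    try:
        return accuracy(np.asarray(tbv, float), gebv)
    except UndefinedMetricError:
        return None
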