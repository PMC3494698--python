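"""Mixed-model solver for the equivalent animal model plus SNP back-solving.

The efficiency argument: the mixed model equations of the animal model have
dimension n (individuals), not m (markers).  Solving once in individual
dimension gives the BLUP of breeding values ``g_hat = V_g V^{-1} (y - X b_hat)``,
and the BLUP of every SNP effect follows from a single matrix-vector
product, ``beta_hat = D W' V^{-1} (y - X b_hat)``, with no inverse of V_g.
``snp_blup_direct`` solves the same problem in marker dimension and serves
as an independent oracle in the test-suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg as sla

from .genomic_data import GenotypeMatrix, ValidationError
from .relationship import EffectVariances, design_matrix

__all__ = [
    "NumericalError",
    "FitResult",
    "animal_model_blup",
    "backsolve_snp_effects",
    "snp_blup_direct",
    "predict_gebv",
    "gblup_fit",
]

logger = logging.getLogger("fastbayesa")


class NumericalError(Exception):
    """Factorization failure that jitter could not repair."""


@dataclass
class FitResult:
    """Outcome of a BLUP or EM fit on a training set."""

    fixed_effects: np.ndarray
    snp_effects: np.ndarray
    gebv: np.ndarray
    effect_variances: EffectVariances
    residual_variance: float
    individuals: list[str] = field(default_factory=list)
    locus_ids: list[str] = field(default_factory=list)
    centered: bool = True
    centering_freqs: np.ndarray | None = None
    converged: bool = True
    n_iterations: int = 1
    prior: object | None = None
    trace: object | None = None


def _solve_spd(V: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve V x = rhs for symmetric positive definite V; jitter on failure."""
    try:
        cho = sla.cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        n = V.shape[0]
        jitter = 1e-8 * np.trace(V) / n
        logger.warning(
            "covariance factorization failed; retrying with jitter %.3g on the diagonal",
            jitter,
        )
        try:
            cho = sla.cho_factor(V + jitter * np.eye(n), lower=True, check_finite=False)
        except np.linalg.LinAlgError as err:
            raise NumericalError("phenotypic covariance not positive definite") from err
    return sla.cho_solve(cho, rhs, check_finite=False)


def animal_model_blup(
    y: np.ndarray,
    X: np.ndarray,
    genotypes: GenotypeMatrix | np.ndarray,
    variances: EffectVariances,
    residual_variance: float,
    center: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """GLS fixed effects and BLUP breeding values from the animal model.

    Returns ``(b_hat, g_hat, projected_residual)`` where
    ``projected_residual = V^{-1} (y - X b_hat)`` is retained so SNP effects
    can be back-solved with one extra matrix-vector product.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W = design_matrix(genotypes, center=center)
    n = y.shape[0]
    if X.shape[0] != n or W.shape[0] != n:
        raise ValidationError("y, X and genotypes have inconsistent row counts")
    if W.shape[1] != len(variances):
        raise ValidationError("effect-variance vector length != number of loci")

    Vg = (W * variances.values) @ W.T
    V = Vg + residual_variance * np.eye(n)
    ViX = _solve_spd(V, X)
    XtViX = X.T @ ViX
    cond = np.linalg.cond(XtViX)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValidationError(
            "fixed-effect design is rank deficient (collinear columns "
            f"{_collinear_columns(X)})"
        )
    b_hat = np.linalg.solve(XtViX, ViX.T @ y)
    resid = y - X @ b_hat
    projected = _solve_spd(V, resid)
    g_hat = Vg @ projected
    return b_hat, g_hat, projected


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Indices of design columns involved in a rank deficiency (diagnostic)."""
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max(initial=0.0) * 1e-10
    return [int(i) for i in np.flatnonzero(diag <= tol)]


def backsolve_snp_effects(
    genotypes: GenotypeMatrix | np.ndarray,
    variances: EffectVariances,
    projected_residual: np.ndarray,
    center: bool = True,
) -> np.ndarray:
    """SNP-effect BLUP from the animal-model solution: beta = D W' V^{-1}(y - Xb)."""
    W = design_matrix(genotypes, center=center)
    projected_residual = np.asarray(projected_residual, dtype=float)
    if W.shape[0] != projected_residual.shape[0]:
        raise ValidationError("projected residual length != number of individuals")
    if W.shape[1] != len(variances):
        raise ValidationError("effect-variance vector length != number of loci")
    return variances.values * (W.T @ projected_residual)


def snp_blup_direct(
    y: np.ndarray,
    X: np.ndarray,
    genotypes: GenotypeMatrix | np.ndarray,
    variances: EffectVariances,
    residual_variance: float,
    center: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint Henderson equations in marker dimension (independent oracle).

    Solves ``[X'X, X'W; W'X, W'W + sigma2_e D^{-1}] [b; beta] = [X'y; W'y]``,
    the exact ridge/BLUP solution.  Intended for moderate m only.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W = design_matrix(genotypes, center=center)
    m = W.shape[1]
    p = X.shape[1]
    lhs = np.empty((p + m, p + m))
    lhs[:p, :p] = X.T @ X
    lhs[:p, p:] = X.T @ W
    lhs[p:, :p] = lhs[:p, p:].T
    lhs[p:, p:] = W.T @ W + residual_variance * np.diag(1.0 / variances.values)
    rhs = np.concatenate([X.T @ y, W.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[:p], sol[p:]


def predict_gebv(
    genotypes: GenotypeMatrix | np.ndarray,
    snp_effects: np.ndarray,
    centering_freqs: np.ndarray | None = None,
    train_locus_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """GEBV of (validation) individuals: row sums of W * beta.

    ``centering_freqs`` must be the *training* allele frequencies so that
    training and validation GEBV share one centering convention.
    """
    snp_effects = np.asarray(snp_effects, dtype=float)
    if isinstance(genotypes, GenotypeMatrix) and train_locus_ids is not None:
        if list(train_locus_ids) != genotypes.locus_ids:
            first = next(
                (a for a, b in zip(train_locus_ids, genotypes.locus_ids) if a != b),
                "(length mismatch)",
            )
            raise ValidationError(
                f"validation loci do not match training loci, first mismatch: {first!r}"
            )
    W = design_matrix(
        genotypes,
        center=centering_freqs is not None,
        freqs=centering_freqs,
    )
    if W.shape[1] != snp_effects.shape[0]:
        raise ValidationError("effect vector length != number of loci")
    return W @ snp_effects


def gblup_fit(
    y: np.ndarray,
    X: np.ndarray,
    genotypes: GenotypeMatrix,
    vc,
    center: bool = True,
) -> FitResult:
    """GBLUP: the animal-model fit with one common marker variance."""
    from .relationship import gblup_marker_variance

    freqs = genotypes.allele_freqs()
    common = gblup_marker_variance(vc, freqs)
    D = EffectVariances.common(common, genotypes.n_loci)
    b_hat, g_hat, projected = animal_model_blup(
        y, X, genotypes, D, vc.residual_variance, center=center
    )
    beta = backsolve_snp_effects(genotypes, D, projected, center=center)
    return FitResult(
        fixed_effects=b_hat,
        snp_effects=beta,
        gebv=g_hat,
        effect_variances=D,
        residual_variance=vc.residual_variance,
        individuals=list(genotypes.individuals),
        locus_ids=genotypes.locus_ids,
        centered=center,
        centering_freqs=freqs if center else None,
    )
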