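"""Marker-based covariance of genomic breeding values.

The SNP effect model ``y = Xb + M beta + e`` with ``beta_j ~ N(0, sigma2_j)``
is equivalent to an animal model whose breeding-value covariance is
``V_g = W D W'``, where ``W`` is the dosage design (optionally centered by
twice the allele frequency) and ``D = diag(sigma2_1, ..., sigma2_m)``.  With
a common effect variance ``sigma2_g / sum_j 2 p_j (1 - p_j)`` this is GBLUP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genomic_data import GenotypeMatrix, ValidationError, VarianceComponents

__all__ = [
    "EffectVariances",
    "GenomicCovariance",
    "design_matrix",
    "gblup_marker_variance",
    "weighted_genomic_covariance",
]

logger = logging.getLogger("fastbayesa")


@dataclass
class EffectVariances:
    """Per-SNP effect variances: the diagonal of D (trait units squared)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("effect variances must be a 1-D vector")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValidationError("effect variances must be finite and > 0")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def common(cls, variance: float, m: int) -> "EffectVariances":
        return cls(np.full(m, float(variance)))


@dataclass
class GenomicCovariance:
    """Dense n x n covariance of genomic breeding values, V_g = W D W'."""

    matrix: np.ndarray
    individuals: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or len(self.individuals) != n:
            raise ValidationError("covariance matrix / individual list mismatch")
        asym = np.abs(self.matrix - self.matrix.T).max(initial=0.0)
        if asym > 1e-10 * max(1.0, np.abs(self.matrix).max(initial=0.0)):
            raise ValidationError(f"covariance not symmetric (max asymmetry {asym:g})")


def design_matrix(
    genotypes: GenotypeMatrix | np.ndarray,
    center: bool = True,
    freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Dosage design matrix W, optionally centered by twice the allele frequency.

    A plain ndarray is passed through untouched (it is already a design).
    ``freqs`` overrides the panel's own frequencies, which matters when a
    validation panel must be centered with training-set frequencies.
    """
    if isinstance(genotypes, np.ndarray):
        return np.asarray(genotypes, dtype=float)
    W = genotypes.dosages.astype(float)
    if center:
        p = genotypes.allele_freqs() if freqs is None else np.asarray(freqs, dtype=float)
        if p.shape[0] != W.shape[1]:
            raise ValidationError("centering frequency vector length != number of loci")
        W = W - 2.0 * p
    return W


def gblup_marker_variance(vc: VarianceComponents, freqs: np.ndarray) -> float:
    """Common SNP effect variance implied by the genetic variance.

    Returns ``sigma2_g / sum_j 2 p_j (1 - p_j)``, the variance each SNP
    effect must have for the markers to jointly explain ``sigma2_g`` under
    Hardy-Weinberg and linkage equilibrium.
    """
    freqs = np.asarray(freqs, dtype=float)
    denom = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    if denom <= 0.0:
        raise ValidationError(
            "sum of 2p(1-p) over loci is zero: all loci monomorphic, cannot map "
            "genetic variance onto marker effect variance"
        )
    return vc.genetic_variance / denom


def weighted_genomic_covariance(
    genotypes: GenotypeMatrix | np.ndarray,
    variances: EffectVariances,
    center: bool = True,
) -> GenomicCovariance:
    """V_g = W D W' with D the per-SNP effect variances."""
    W = design_matrix(genotypes, center=center)
    if W.shape[1] != len(variances):
        raise ValidationError(
            f"{W.shape[1]} loci but {len(variances)} effect variances"
        )
    Vg = (W * variances.values) @ W.T
    Vg = 0.5 * (Vg + Vg.T)  # enforce exact symmetry against rounding
    individuals = (
        genotypes.individuals
        if isinstance(genotypes, GenotypeMatrix)
        else [str(i) for i in range(W.shape[0])]
    )
    return GenomicCovariance(matrix=Vg, individuals=list(individuals))
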