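"""Core data containers and text I/O for genomic prediction.

Genotypes are stored as counted-allele dosages in {0, 1, 2}; which allele is
counted is arbitrary but fixed per locus, and all downstream estimation is
invariant to the choice as long as the model contains an intercept.  Missing
genotypes are rejected rather than imputed: the intended data sources
(the forward simulator and complete SNP-panel exports) have no missingness.

File dialect: UTF-8 TSV throughout, ``.`` for a missing parent id in
pedigrees, map positions in Morgans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicDataError",
    "FormatError",
    "ValidationError",
    "LocusInfo",
    "GenotypeMatrix",
    "PhenotypeTable",
    "PedigreeTable",
    "VarianceComponents",
    "allele_frequencies",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "write_fit_result",
    "read_effects",
]


class GenomicDataError(Exception):
    """Base class for data-layer errors."""


class FormatError(GenomicDataError):
    """Malformed input file (bad row length, missing header, empty file)."""


class ValidationError(GenomicDataError):
    """Structurally valid input violating a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusInfo:
    """Map and frequency information for one biallelic locus.

    ``position`` is the map distance in Morgans from the chromosome start;
    ``allele_freq`` is the frequency of the counted allele.  ``is_qtl`` is
    simulator provenance only and never consulted by estimation code.
    """

    locus_id: str
    chromosome: int = 0
    position: float = 0.0
    allele_freq: float = np.nan
    is_qtl: bool = False

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValidationError(f"locus {self.locus_id}: negative map position")
        if np.isfinite(self.allele_freq) and not 0.0 <= self.allele_freq <= 1.0:
            raise ValidationError(
                f"locus {self.locus_id}: allele frequency {self.allele_freq} outside [0, 1]"
            )


@dataclass
class GenotypeMatrix:
    """An n-individuals x m-loci dosage matrix with its locus map.

    This is the ``M`` of the SNP effect model: entry (i, j) counts copies of
    the counted allele of locus j carried by individual i.
    """

    individuals: list[str]
    loci: list[LocusInfo]
    dosages: np.ndarray  # (n, m) int8

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        n, m = self.shape
        if len(self.individuals) != n or len(self.loci) != m:
            raise ValidationError(
                f"dosage matrix is {n}x{m} but {len(self.individuals)} individuals "
                f"and {len(self.loci)} loci were given"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {self.dosages[i, j]!r} for individual {self.individuals[i]!r} "
                f"at locus {self.loci[j].locus_id!r} is not in {{0, 1, 2}}"
            )
        ids = [loc.locus_id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate locus ids in panel")
        self.dosages = self.dosages.astype(np.int8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosages.shape

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    def allele_freqs(self) -> np.ndarray:
        """Per-locus counted-allele frequencies; stored values if present,
        otherwise computed from column means."""
        stored = np.array([loc.allele_freq for loc in self.loci], dtype=float)
        if np.all(np.isfinite(stored)):
            return stored
        return allele_frequencies(self)

    def subset_individuals(self, index: Sequence[int]) -> "GenotypeMatrix":
        index = list(index)
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in index],
            loci=self.loci,
            dosages=self.dosages[index, :],
        )


@dataclass
class PhenotypeTable:
    """Trait records with fixed-effect covariates.

    ``frame`` has one row per phenotyped individual with columns
    ``individual_id``, ``value`` and one column per covariate.  An intercept
    column of ones is always present.
    """

    frame: pd.DataFrame
    covariate_names: list[str] = field(default_factory=lambda: ["intercept"])

    def __post_init__(self) -> None:
        required = {"individual_id", "value"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"phenotype table missing columns: {sorted(missing)}")
        if "intercept" not in self.frame.columns:
            self.frame = self.frame.assign(intercept=1.0)
        if "intercept" not in self.covariate_names:
            self.covariate_names = ["intercept", *self.covariate_names]
        if self.frame["individual_id"].duplicated().any():
            dup = self.frame["individual_id"][self.frame["individual_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate phenotype record for individual {dup!r}")

    def aligned_to(self, genotypes: GenotypeMatrix) -> "PhenotypeTable":
        """Rows reordered to the genotype matrix; every id must resolve."""
        idx = self.frame.set_index("individual_id")
        missing = [i for i in genotypes.individuals if i not in idx.index]
        if missing:
            raise ValidationError(
                f"{len(missing)} genotyped individuals lack phenotypes, first: {missing[0]!r}"
            )
        sub = idx.loc[genotypes.individuals].reset_index()
        return PhenotypeTable(sub, covariate_names=list(self.covariate_names))

    @property
    def values(self) -> np.ndarray:
        return self.frame["value"].to_numpy(dtype=float)

    @property
    def design_matrix(self) -> np.ndarray:
        return self.frame[self.covariate_names].to_numpy(dtype=float)


@dataclass
class PedigreeTable:
    """Pedigree records: columns individual_id, sire_id, dam_id, sex, generation.

    Missing parents (pedigree founders) are ``None`` in memory and ``.`` on
    disk.  Parents must appear in strictly earlier generations, which also
    rules out ancestry cycles.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"individual_id", "sire_id", "dam_id", "sex", "generation"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValidationError(f"pedigree missing columns: {sorted(missing)}")
        gen = dict(zip(self.frame["individual_id"], self.frame["generation"]))
        for row in self.frame.itertuples(index=False):
            for parent in (row.sire_id, row.dam_id):
                if parent is None or (isinstance(parent, float) and np.isnan(parent)):
                    continue
                if parent not in gen:
                    raise ValidationError(
                        f"parent {parent!r} of {row.individual_id!r} not in pedigree"
                    )
                if gen[parent] >= row.generation:
                    raise ValidationError(
                        f"parent {parent!r} of {row.individual_id!r} is not in an "
                        f"earlier generation"
                    )

    def generation_ids(self, generation: int) -> list[str]:
        mask = self.frame["generation"] == generation
        return self.frame.loc[mask, "individual_id"].tolist()


@dataclass(frozen=True)
class VarianceComponents:
    """Additive-genetic and residual variance on the trait scale."""

    genetic_variance: float
    residual_variance: float

    def __post_init__(self) -> None:
        if not (self.genetic_variance > 0 and self.residual_variance > 0):
            raise ValidationError("variance components must be strictly positive")

    @property
    def heritability(self) -> float:
        return self.genetic_variance / (self.genetic_variance + self.residual_variance)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def allele_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    """Counted-allele frequency per locus: column dosage sum / 2n."""
    n = genotypes.n_individuals
    if n < 1:
        raise ValidationError("cannot compute allele frequencies with zero individuals")
    return genotypes.dosages.mean(axis=0, dtype=float) / 2.0


def read_genotypes(path: str | Path, format: str = "tsv_dosage") -> GenotypeMatrix:
    """Read a dosage matrix from TSV or PLINK ``.raw``.

    TSV dialect: header row of locus ids, first column the individual id, one
    row per individual.  PLINK ``.raw``: space-delimited with the standard six
    leading columns (FID IID PAT MAT SEX PHENOTYPE); ``NA`` dosages rejected.
    """
    path = Path(path)
    if format == "tsv_dosage":
        sep, skip_cols = "\t", 1
    elif format == "plink_raw":
        sep, skip_cols = None, 6
    else:
        raise ValueError(f"unknown genotype format {format!r}")

    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty genotype file")
    header = lines[0].split(sep)
    if len(header) <= skip_cols:
        raise FormatError(f"{path}: header has no locus columns")
    locus_ids = header[skip_cols:]
    individuals: list[str] = []
    rows: list[list[str]] = []
    for ln_no, line in enumerate(lines[1:], start=2):
        fields_ = line.split(sep)
        if len(fields_) != len(header):
            raise FormatError(
                f"{path} line {ln_no}: expected {len(header)} fields, got {len(fields_)}"
            )
        individuals.append(fields_[1] if format == "plink_raw" else fields_[0])
        rows.append(fields_[skip_cols:])
    dosages = np.empty((len(rows), len(locus_ids)), dtype=np.int8)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            if cell not in ("0", "1", "2"):
                raise ValidationError(
                    f"{path} individual {individuals[i]!r} locus {locus_ids[j]!r}: "
                    f"dosage {cell!r} is not in {{0, 1, 2}}"
                )
            dosages[i, j] = int(cell)
    # PLINK .raw encodes the counted allele in the header as ID_A; keep as-is.
    loci = [LocusInfo(locus_id=lid) for lid in locus_ids]
    geno = GenotypeMatrix(individuals=individuals, loci=loci, dosages=dosages)
    freqs = allele_frequencies(geno)
    geno.loci = [
        LocusInfo(locus_id=l.locus_id, chromosome=l.chromosome, position=l.position,
                  allele_freq=f, is_qtl=l.is_qtl)
        for l, f in zip(loci, freqs)
    ]
    return geno


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dosage dialect accepted by :func:`read_genotypes`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("individual_id\t" + "\t".join(genotypes.locus_ids) + "\n")
        for ind, row in zip(genotypes.individuals, genotypes.dosages):
            fh.write(ind + "\t" + "\t".join(str(int(d)) for d in row) + "\n")


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    frame = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    covars = [c for c in frame.columns if c not in ("individual_id", "value")]
    return PhenotypeTable(frame, covariate_names=covars or ["intercept"])


def write_phenotypes(table: PhenotypeTable, path: str | Path) -> None:
    cols = ["individual_id", "value", *[c for c in table.covariate_names]]
    table.frame[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_pedigree(path: str | Path) -> PedigreeTable:
    frame = pd.read_csv(
        path, sep="\t",
        dtype={"individual_id": str, "sire_id": str, "dam_id": str, "sex": str},
        na_values=["."], keep_default_na=False,
    )
    frame["sire_id"] = frame["sire_id"].where(frame["sire_id"].notna(), None)
    frame["dam_id"] = frame["dam_id"].where(frame["dam_id"].notna(), None)
    frame["generation"] = frame["generation"].astype(int)
    return PedigreeTable(frame)


def write_pedigree(pedigree: PedigreeTable, path: str | Path) -> None:
    out = pedigree.frame.copy()
    for col in ("sire_id", "dam_id"):
        out[col] = out[col].map(
            lambda v: "." if v is None or (isinstance(v, float) and np.isnan(v)) else v
        )
    out.to_csv(path, sep="\t", index=False)


def write_fit_result(result, prefix: str | Path) -> None:
    """Serialize a fit: per-SNP effects, per-individual GEBV and run metadata.

    Writes ``<prefix>.effects.tsv`` (locus id + effect at full double
    precision), ``<prefix>.gebv.tsv`` and ``<prefix>.meta.json``.
    """
    prefix = Path(prefix)
    eff = pd.DataFrame({"locus_id": result.locus_ids, "effect": result.snp_effects})
    eff.to_csv(prefix.with_suffix(".effects.tsv"), sep="\t", index=False,
               float_format="%.17g")
    gebv = pd.DataFrame({"individual_id": result.individuals, "gebv": result.gebv})
    gebv.to_csv(prefix.with_suffix(".gebv.tsv"), sep="\t", index=False,
                float_format="%.17g")
    meta = {
        "residual_variance": float(result.residual_variance),
        "converged": bool(result.converged),
        "n_iterations": int(result.n_iterations),
        "centered": bool(result.centered),
    }
    if result.prior is not None:
        meta["prior_df"] = float(result.prior.df)
        meta["prior_scale"] = float(result.prior.scale)
    with prefix.with_suffix(".meta.json").open("w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)


def read_effects(path: str | Path) -> pd.DataFrame:
    """Read back an ``.effects.tsv`` written by :func:`write_fit_result`."""
    return pd.read_csv(path, sep="\t", dtype={"locus_id": str})
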