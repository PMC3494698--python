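"""Forward-in-time simulator of pedigreed livestock populations.

The study design this reproduces: a historical population of effective size
Ne is random-mated to mutation-drift equilibrium, gradually expanded, and a
structured pedigree (sires x dams, fixed offspring numbers) is bred from
founders sampled out of the expanded generation.  Meiosis places a
Poisson-distributed number of crossovers uniformly on each chromosome, so
recombination follows the Haldane map ``r = (1 - exp(-2d))/2``.  SNP panel
and QTL are drawn by minor-allele-frequency filters in the founder cohort,
QTL get gamma-distributed (or constant-variance) allele-substitution
effects rescaled to an exact target genetic variance, and phenotypes add
normal noise sized by the heritability.

Several design constants of the original study are reconstructed rather
than copied (see docs/methods.md): the defaults below reproduce its printed
effective-segment numbers (Me 241/543/1010 for 2/5/10 chromosomes of 1
Morgan at Ne=500) and training-set sizes (220 founders + 400 offspring per
generation -> 620/1020/2220).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .genomic_data import (
    GenotypeMatrix,
    LocusInfo,
    PedigreeTable,
    PhenotypeTable,
    ValidationError,
)

__all__ = [
    "SimScenario",
    "QTLTruth",
    "SimulatedDataset",
    "InsufficientQtlError",
    "expected_me",
    "burn_in_drift",
    "meiosis_gamete",
    "random_mating_generation",
    "build_pedigree_generations",
    "select_panel_and_qtl",
    "assign_qtl_effects",
    "simulate_phenotypes",
    "simulate_scenario",
    "load_scenario",
    "scenario_names",
]

logger = logging.getLogger("fastbayesa")


class InsufficientQtlError(ValidationError):
    """Too few polymorphic QTL candidates after MAF filtering."""


def expected_me(ne: float, genome_length: float) -> int:
    """Effective number of independently segregating chromosome segments.

    ``Me = 2 Ne L / ln(4 Ne L)`` with L the total genome length in Morgans,
    rounded to the nearest integer for reporting.
    """
    if ne < 1 or genome_length <= 0:
        raise ValidationError("need Ne >= 1 and genome length > 0")
    x = 2.0 * ne * genome_length
    return int(round(x / math.log(2.0 * x)))


@dataclass(frozen=True)
class SimScenario:
    """Full parameterization of one simulated scenario.

    ``pedigree_generations`` counts offspring generations bred after the
    founder cohort (generation 0); the last ``validation_generations`` of
    them are held out for validation, everything earlier trains.
    ``n_qtl`` overrides ``qtl_me_multiplier`` when set.
    """

    name: str = "custom"
    # historical population
    effective_size: int = 500
    burnin_generations: int = 1000
    expanded_size: int = 1000
    expansion_generations: int = 5
    # pedigree design
    n_sires: int = 20
    n_dams: int = 200
    dams_per_sire: int = 10
    offspring_per_dam: tuple[int, int] = (1, 1)  # (males, females)
    pedigree_generations: int = 7
    validation_generations: int = 5
    # genome
    chromosomes: int = 2
    chrom_length: float = 1.0  # Morgans
    loci_per_chrom: int = 2000
    mutation_rate: float = 2.5e-5  # per meiosis per locus, allele-flipping
    initial_allele_freq: float = 0.5
    # panel / QTL
    maf_min_snp: float = 0.05
    maf_min_qtl: float = 0.05
    n_qtl: int | None = None
    qtl_me_multiplier: float | None = 0.1
    qtl_candidate_multiplier: float = 2.0
    qtl_variance_mode: str = "hetero"  # or "const"
    gamma_shape: float = 0.4
    gamma_scale: float = 1.66
    qtl_in_panel: bool = False
    # trait
    heritability: float = 0.5
    genetic_variance_target: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sires * self.dams_per_sire != self.n_dams:
            raise ValidationError("need n_sires * dams_per_sire == n_dams")
        if min(self.offspring_per_dam) < 1:
            raise ValidationError("offspring counts must be positive")
        if not 0.0 < self.heritability < 1.0:
            raise ValidationError("heritability must be in (0, 1)")
        if self.qtl_variance_mode not in ("hetero", "const"):
            raise ValidationError("qtl_variance_mode must be 'hetero' or 'const'")
        if self.validation_generations >= self.pedigree_generations:
            raise ValidationError(
                "pedigree_generations must exceed validation_generations"
            )
        males = self.n_dams * self.offspring_per_dam[0]
        females = self.n_dams * self.offspring_per_dam[1]
        if males < self.n_sires or females < self.n_dams:
            raise ValidationError(
                "offspring per generation cannot supply the next generation's parents"
            )
        if self.expanded_size < self.n_sires + self.n_dams:
            raise ValidationError("expanded population smaller than founder demand")

    # -- derived quantities -------------------------------------------------

    @property
    def total_genome_length(self) -> float:
        return self.chromosomes * self.chrom_length

    @property
    def me(self) -> int:
        return expected_me(self.effective_size, self.total_genome_length)

    @property
    def resolved_n_qtl(self) -> int:
        if self.n_qtl is not None:
            return self.n_qtl
        if self.qtl_me_multiplier is None:
            raise ValidationError("neither n_qtl nor qtl_me_multiplier set")
        return max(1, int(round(self.qtl_me_multiplier * self.me)))

    @property
    def residual_variance(self) -> float:
        return self.genetic_variance_target * (1.0 - self.heritability) / self.heritability

    @property
    def n_founders(self) -> int:
        return self.n_sires + self.n_dams

    @property
    def offspring_per_generation(self) -> int:
        return self.n_dams * sum(self.offspring_per_dam)

    @property
    def training_generations(self) -> int:
        """Number of training generations including the founder cohort."""
        return self.pedigree_generations + 1 - self.validation_generations

    @property
    def training_size(self) -> int:
        return self.n_founders + (self.training_generations - 1) * self.offspring_per_generation

    def locus_positions(self) -> tuple[np.ndarray, np.ndarray]:
        """(chromosome index, position in Morgans) for every simulated locus,
        evenly spaced along each chromosome."""
        per = (np.arange(self.loci_per_chrom) + 0.5) * self.chrom_length / self.loci_per_chrom
        chrom = np.repeat(np.arange(self.chromosomes), self.loci_per_chrom)
        pos = np.tile(per, self.chromosomes)
        return chrom, pos

    def to_yaml(self, path: str | Path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimScenario":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if "offspring_per_dam" in data:
            data["offspring_per_dam"] = tuple(data["offspring_per_dam"])
        return cls(**data)


@dataclass
class QTLTruth:
    """Ground truth of the trait architecture for one replicate."""

    qtl_indices: np.ndarray  # positions among all simulated loci
    effects: np.ndarray  # signed allele-substitution effects
    allele_freqs: np.ndarray  # at the reference (founder) generation
    variance_contributions: np.ndarray  # 2 p q a^2 per QTL

    def __post_init__(self) -> None:
        total = float(np.sum(self.variance_contributions))
        expect = float(np.sum(2 * self.allele_freqs * (1 - self.allele_freqs) * self.effects**2))
        if abs(total - expect) > 1e-9 * max(1.0, total):
            raise ValidationError("inconsistent QTL variance contributions")


@dataclass
class SimulatedDataset:
    """One simulated replicate: panel genotypes per generation plus truth."""

    scenario: SimScenario
    genotypes: list[GenotypeMatrix]  # index = pedigree generation (0 = founders)
    pedigree: PedigreeTable
    tbv: pd.Series  # true breeding value per individual id
    phenotypes: PhenotypeTable
    truth: QTLTruth
    me: int

    def generation_ids(self, generation: int) -> list[str]:
        return self.genotypes[generation].individuals

    def training_genotypes(self) -> GenotypeMatrix:
        """Stacked panel of all training generations (founders first)."""
        gens = self.genotypes[: self.scenario.training_generations]
        dosages = np.vstack([g.dosages for g in gens])
        individuals = [i for g in gens for i in g.individuals]
        stacked = GenotypeMatrix(
            individuals=individuals,
            loci=[replace(l, allele_freq=np.nan) for l in gens[0].loci],
            dosages=dosages,
        )
        freqs = stacked.dosages.mean(axis=0) / 2.0
        stacked.loci = [replace(l, allele_freq=f) for l, f in zip(stacked.loci, freqs)]
        return stacked

    def validation_genotypes(self, offset: int = 1) -> GenotypeMatrix:
        """Panel of the ``offset``-th generation after training (1-based)."""
        if not 1 <= offset <= self.scenario.validation_generations:
            raise ValidationError(
                f"validation offset {offset} outside 1..{self.scenario.validation_generations}"
            )
        return self.genotypes[self.scenario.training_generations - 1 + offset]

    def training_data(self) -> tuple[np.ndarray, np.ndarray, GenotypeMatrix]:
        """(y, X, genotypes) of the training set, rows aligned."""
        G = self.training_genotypes()
        pheno = self.phenotypes.aligned_to(G)
        return pheno.values, pheno.design_matrix, G

    def tbv_of(self, individuals: list[str]) -> np.ndarray:
        return self.tbv.loc[individuals].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# Meiosis and random mating
# ---------------------------------------------------------------------------


def meiosis_gamete(
    parent: np.ndarray,
    positions: np.ndarray,
    chrom_length: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a (2, L) parental chromosome pair.

    Crossover count ~ Poisson(length in Morgans), crossover positions
    uniform, no interference; the starting strand is chosen at random.
    """
    k = rng.poisson(chrom_length)
    start = rng.integers(2)
    if k == 0:
        return parent[start].copy()
    xo = np.sort(rng.uniform(0.0, chrom_length, size=k))
    phase = (start + np.searchsorted(xo, positions)) % 2
    return parent[phase, np.arange(parent.shape[1])]


def _full_gamete(
    genome: np.ndarray,
    chrom_bounds: list[tuple[int, int]],
    chrom_length: float,
    positions: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Whole-genome gamete: independent meiosis per chromosome."""
    out = np.empty(genome.shape[1], dtype=genome.dtype)
    for lo, hi in chrom_bounds:
        out[lo:hi] = meiosis_gamete(genome[:, lo:hi], positions[lo:hi], chrom_length, rng)
    return out


def _mutate(pool: np.ndarray, mu: float, rng: np.random.Generator) -> None:
    """Recurrent two-allele mutation: flip alleles in place at rate mu."""
    if mu <= 0:
        return
    total = pool.size
    k = rng.binomial(total, mu)
    if k:
        flat = rng.integers(0, total, size=k)
        pool.reshape(-1)[flat] ^= 1


def random_mating_generation(
    pool: np.ndarray,
    n_offspring: int,
    scenario: SimScenario,
    rng: np.random.Generator,
    mutate: bool = True,
) -> np.ndarray:
    """One generation of random mating (two distinct parents per offspring)."""
    n = pool.shape[0]
    chrom_bounds = _chrom_bounds(scenario)
    _, positions = scenario.locus_positions()
    sires = rng.integers(0, n, size=n_offspring)
    dams = rng.integers(0, n, size=n_offspring)
    clash = sires == dams
    while clash.any():
        dams[clash] = rng.integers(0, n, size=int(clash.sum()))
        clash = sires == dams
    offspring = np.empty((n_offspring, 2, pool.shape[2]), dtype=pool.dtype)
    for i in range(n_offspring):
        offspring[i, 0] = _full_gamete(pool[sires[i]], chrom_bounds, scenario.chrom_length, positions, rng)
        offspring[i, 1] = _full_gamete(pool[dams[i]], chrom_bounds, scenario.chrom_length, positions, rng)
    if mutate:
        _mutate(offspring, scenario.mutation_rate, rng)
    return offspring


def _chrom_bounds(scenario: SimScenario) -> list[tuple[int, int]]:
    L = scenario.loci_per_chrom
    return [(c * L, (c + 1) * L) for c in range(scenario.chromosomes)]


def burn_in_drift(scenario: SimScenario, rng: np.random.Generator) -> np.ndarray:
    """Historical population: drift to mutation-drift equilibrium, then expand.

    Returns a (expanded_size, 2, n_loci) array of haplotypes.  The initial
    population starts every locus at the configured allele frequency in
    Hardy-Weinberg proportions; expansion grows the census linearly over
    ``expansion_generations``.
    """
    n_loci = scenario.chromosomes * scenario.loci_per_chrom
    pool = (
        rng.random((scenario.effective_size, 2, n_loci)) < scenario.initial_allele_freq
    ).astype(np.int8)
    for _ in range(scenario.burnin_generations):
        pool = random_mating_generation(pool, scenario.effective_size, scenario, rng)
    sizes = np.linspace(
        scenario.effective_size,
        scenario.expanded_size,
        scenario.expansion_generations + 1,
    )[1:]
    for size in np.round(sizes).astype(int):
        pool = random_mating_generation(pool, int(size), scenario, rng)
    return pool


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------


def build_pedigree_generations(
    scenario: SimScenario,
    founders: np.ndarray,
    rng: np.random.Generator,
) -> tuple[PedigreeTable, list[tuple[list[str], np.ndarray]]]:
    """Breed the structured pedigree from the founder haplotypes.

    ``founders`` is a (n_sires + n_dams, 2, L) array; the first ``n_sires``
    rows become the founding sires.  Each sire mates ``dams_per_sire``
    randomly assigned dams; each dam produces a fixed number of male and
    female offspring; the next generation's parents are sampled from the
    offspring.  Returns the pedigree and, per generation, (ids, haplotypes).
    """
    sc = scenario
    if founders.shape[0] != sc.n_founders:
        raise ValidationError("founder array does not match n_sires + n_dams")
    chrom_bounds = _chrom_bounds(sc)
    _, positions = sc.locus_positions()

    rows: list[tuple[str, str | None, str | None, str, int]] = []
    generations: list[tuple[list[str], np.ndarray]] = []

    founder_ids = [f"g0_i{k:04d}" for k in range(sc.n_founders)]
    founder_sex = ["male"] * sc.n_sires + ["female"] * sc.n_dams
    for ind, sex in zip(founder_ids, founder_sex):
        rows.append((ind, None, None, sex, 0))
    generations.append((founder_ids, founders))

    sire_ids = founder_ids[: sc.n_sires]
    sire_geno = founders[: sc.n_sires]
    dam_ids = founder_ids[sc.n_sires:]
    dam_geno = founders[sc.n_sires:]

    off_m, off_f = sc.offspring_per_dam
    for gen in range(1, sc.pedigree_generations + 1):
        n_off = sc.offspring_per_generation
        ids = [f"g{gen}_i{k:04d}" for k in range(n_off)]
        genomes = np.empty((n_off, 2, founders.shape[2]), dtype=founders.dtype)
        sexes: list[str] = []
        # random dam -> sire assignment, dams_per_sire dams each
        order = rng.permutation(sc.n_dams)
        k = 0
        for slot, dam_idx in enumerate(order):
            sire_idx = slot // sc.dams_per_sire
            for sex, count in (("male", off_m), ("female", off_f)):
                for _ in range(count):
                    genomes[k, 0] = _full_gamete(
                        sire_geno[sire_idx], chrom_bounds, sc.chrom_length, positions, rng
                    )
                    genomes[k, 1] = _full_gamete(
                        dam_geno[dam_idx], chrom_bounds, sc.chrom_length, positions, rng
                    )
                    rows.append((ids[k], sire_ids[sire_idx], dam_ids[dam_idx], sex, gen))
                    sexes.append(sex)
                    k += 1
        _mutate(genomes, sc.mutation_rate, rng)
        generations.append((ids, genomes))

        males = [i for i, s in enumerate(sexes) if s == "male"]
        females = [i for i, s in enumerate(sexes) if s == "female"]
        if len(males) < sc.n_sires or len(females) < sc.n_dams:
            raise ValidationError("not enough offspring of a sex to continue pedigree")
        sire_pick = rng.choice(males, size=sc.n_sires, replace=False)
        dam_pick = rng.choice(females, size=sc.n_dams, replace=False)
        sire_ids = [ids[i] for i in sire_pick]
        sire_geno = genomes[sire_pick]
        dam_ids = [ids[i] for i in dam_pick]
        dam_geno = genomes[dam_pick]

    frame = pd.DataFrame(
        rows, columns=["individual_id", "sire_id", "dam_id", "sex", "generation"]
    )
    return PedigreeTable(frame), generations


# ---------------------------------------------------------------------------
# Panel / QTL selection and trait construction
# ---------------------------------------------------------------------------


def select_panel_and_qtl(
    freqs: np.ndarray,
    candidate_indices: np.ndarray,
    scenario: SimScenario,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """MAF-filter the SNP panel and draw the QTL among candidates.

    ``freqs`` are counted-allele frequencies at the reference generation.
    Thresholds are inclusive (MAF >= cutoff retains the locus).  Raises
    :class:`InsufficientQtlError` when fewer than ``n_qtl`` candidates
    remain polymorphic enough; the caller may retry with a fresh placement.
    """
    maf = np.minimum(freqs, 1.0 - freqs)
    is_candidate = np.zeros(freqs.shape[0], dtype=bool)
    is_candidate[candidate_indices] = True

    eligible_qtl = np.flatnonzero(is_candidate & (maf >= scenario.maf_min_qtl))
    n_qtl = scenario.resolved_n_qtl
    if eligible_qtl.size < n_qtl:
        raise InsufficientQtlError(
            f"only {eligible_qtl.size} of {candidate_indices.size} QTL candidates "
            f"have MAF >= {scenario.maf_min_qtl}, need {n_qtl}"
        )
    qtl = np.sort(rng.choice(eligible_qtl, size=n_qtl, replace=False))

    snp_mask = maf >= scenario.maf_min_snp
    if not scenario.qtl_in_panel:
        snp_mask &= ~is_candidate
    snp = np.flatnonzero(snp_mask)
    if snp.size == 0:
        raise InsufficientQtlError("no polymorphic SNPs left after MAF filtering")
    return snp, qtl


def assign_qtl_effects(
    qtl_indices: np.ndarray,
    qtl_freqs: np.ndarray,
    scenario: SimScenario,
    rng: np.random.Generator,
) -> QTLTruth:
    """Draw signed allele-substitution effects and scale to the target variance.

    hetero mode: |a| ~ Gamma(shape, scale), random sign; const mode:
    a = +/- sqrt(c / 2pq) so every QTL contributes equal variance.  A single
    common factor then rescales all effects so the summed contributions
    2 p q a^2 hit ``genetic_variance_target`` exactly.
    """
    n = qtl_indices.shape[0]
    p = np.asarray(qtl_freqs, dtype=float)
    if n == 0:  # no-QTL trait: zero breeding values, phenotypes pure noise
        return QTLTruth(
            qtl_indices=qtl_indices,
            effects=np.zeros(0),
            allele_freqs=p,
            variance_contributions=np.zeros(0),
        )
    het = 2.0 * p * (1.0 - p)
    if np.any(het <= 0):
        raise AssertionError("monomorphic QTL must be excluded by the MAF filter")
    signs = rng.choice((-1.0, 1.0), size=n)
    if scenario.qtl_variance_mode == "hetero":
        a = signs * rng.gamma(scenario.gamma_shape, scenario.gamma_scale, size=n)
    else:
        c = scenario.genetic_variance_target / n
        a = signs * np.sqrt(c / het)
    total = float(np.sum(het * a**2))
    if total <= 0:
        raise InsufficientQtlError("all sampled QTL effects are zero, cannot scale")
    a *= math.sqrt(scenario.genetic_variance_target / total)
    return QTLTruth(
        qtl_indices=qtl_indices,
        effects=a,
        allele_freqs=p,
        variance_contributions=het * a**2,
    )


def simulate_phenotypes(
    tbv: pd.Series,
    scenario: SimScenario,
    rng: np.random.Generator,
) -> PhenotypeTable:
    """Phenotype = TBV + N(0, sigma2_g (1 - h2) / h2) noise."""
    noise = rng.normal(0.0, math.sqrt(scenario.residual_variance), size=len(tbv))
    frame = pd.DataFrame(
        {
            "individual_id": tbv.index,
            "value": tbv.to_numpy(dtype=float) + noise,
            "intercept": 1.0,
        }
    )
    return PhenotypeTable(frame)


def simulate_scenario(scenario: SimScenario) -> SimulatedDataset:
    """End-to-end generation of one replicate (deterministic given the seed)."""
    rng = np.random.default_rng(scenario.seed)
    sc = scenario
    logger.info(
        "simulating scenario %s: Ne=%d, %d chrom x %.2f M, %d loci, %d QTL, h2=%.2f",
        sc.name, sc.effective_size, sc.chromosomes, sc.chrom_length,
        sc.chromosomes * sc.loci_per_chrom, sc.resolved_n_qtl, sc.heritability,
    )

    pool = burn_in_drift(sc, rng)
    founder_rows = rng.choice(pool.shape[0], size=sc.n_founders, replace=False)
    founders = pool[founder_rows]
    pedigree, generations = build_pedigree_generations(sc, founders, rng)

    # Reference generation for MAF filtering and variance scaling: founders.
    ref_freqs = founders.sum(axis=1).mean(axis=0) / 2.0
    n_candidates = max(
        sc.resolved_n_qtl, int(round(sc.qtl_candidate_multiplier * sc.resolved_n_qtl))
    )
    n_loci = sc.chromosomes * sc.loci_per_chrom
    snp_idx = qtl_idx = None
    for attempt in range(10):
        candidate_idx = rng.choice(n_loci, size=n_candidates, replace=False)
        try:
            snp_idx, qtl_idx = select_panel_and_qtl(ref_freqs, candidate_idx, sc, rng)
            break
        except InsufficientQtlError as err:
            logger.warning("QTL candidate placement retry %d: %s", attempt + 1, err)
    else:
        raise InsufficientQtlError(
            "could not place enough polymorphic QTL candidates in 10 attempts"
        )

    truth = assign_qtl_effects(qtl_idx, ref_freqs[qtl_idx], sc, rng)

    chrom, pos = sc.locus_positions()
    panel_matrices: list[GenotypeMatrix] = []
    tbv_parts: list[pd.Series] = []
    for ids, genomes in generations:
        dosages = genomes.sum(axis=1, dtype=np.int8)
        tbv_parts.append(
            pd.Series(dosages[:, qtl_idx].astype(float) @ truth.effects, index=ids)
        )
        panel = dosages[:, snp_idx]
        freqs = panel.mean(axis=0) / 2.0
        loci = [
            LocusInfo(
                locus_id=f"snp_c{chrom[j]}_{j % sc.loci_per_chrom:05d}",
                chromosome=int(chrom[j]),
                position=float(pos[j]),
                allele_freq=float(f),
                is_qtl=False,
            )
            for j, f in zip(snp_idx, freqs)
        ]
        panel_matrices.append(
            GenotypeMatrix(individuals=list(ids), loci=loci, dosages=panel)
        )

    tbv = pd.concat(tbv_parts)
    phenotypes = simulate_phenotypes(tbv, sc, rng)
    return SimulatedDataset(
        scenario=sc,
        genotypes=panel_matrices,
        pedigree=pedigree,
        tbv=tbv,
        phenotypes=phenotypes,
        truth=truth,
        me=sc.me,
    )


# ---------------------------------------------------------------------------
# Scenario library
# ---------------------------------------------------------------------------


def _scenario_dir() -> Path:
    return Path(__file__).parent / "scenarios"


def scenario_names() -> list[str]:
    return sorted(p.stem for p in _scenario_dir().glob("*.yaml"))


def load_scenario(name: str, **overrides) -> SimScenario:
    """Load a shipped scenario (A1-A4, B1-B5) with optional field overrides."""
    path = _scenario_dir() / f"{name}.yaml"
    if not path.exists():
        raise ValidationError(
            f"unknown scenario {name!r}; available: {', '.join(scenario_names())}"
        )
    base = SimScenario.from_yaml(path)
    return replace(base, **overrides) if overrides else base
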