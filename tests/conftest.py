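"""Shared fixtures: a desk-scale version of the standard few-QTL scenario.

The desk profile keeps every structural rule of the study design (QTL count
= 0.1 x Me, gamma effect sizes, MAF filters, sire x dam pedigree, five
validation generations, h2 = 0.5) but shrinks the historical population and
the genome so a ten-replicate, four-method comparison runs in minutes.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fastbayesa import (
    BayesAPrior,
    EMOptions,
    ExperimentConfig,
    McmcOptions,
    SimScenario,
    run_experiment,
    simulate_scenario,
)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Replicate seeds for the paired desk-scale experiment.
DESK_SEED_BASE = 1000
DESK_REPLICATES = 10


def desk_scenario(**overrides) -> SimScenario:
    # dimensionless ratios follow the full design: burn-in = 2 Ne generations,
    # 4 Ne mu = 0.05, training ~ 8.7 Me at h2 = 0.5
    base = dict(
        name="A1-desk",
        effective_size=100,
        burnin_generations=200,
        mutation_rate=1.25e-4,
        expanded_size=300,
        expansion_generations=3,
        n_sires=20,
        n_dams=100,
        dams_per_sire=5,
        offspring_per_dam=(1, 1),
        pedigree_generations=7,
        validation_generations=5,
        chromosomes=2,
        chrom_length=1.0,
        loci_per_chrom=400,
        heritability=0.5,
        seed=1,
    )
    base.update(overrides)
    return SimScenario(**base)


@pytest.fixture(scope="session")
def desk_a1() -> SimScenario:
    return desk_scenario()


@pytest.fixture(scope="session")
def desk_datasets(desk_a1):
    """Ten paired desk-scale replicates of the few-QTL scenario."""
    from dataclasses import replace

    return [
        simulate_scenario(replace(desk_a1, seed=DESK_SEED_BASE + r))
        for r in range(DESK_REPLICATES)
    ]


@pytest.fixture(scope="session")
def desk_report(desk_a1):
    """All four methods on the ten desk replicates (paired by seed)."""
    config = ExperimentConfig(
        scenario=desk_a1,
        methods=("gblup", "fastbayesa", "bayesa", "bayesb"),
        replicates=DESK_REPLICATES,
        seed_base=DESK_SEED_BASE,
        em_options=EMOptions(),
        mcmc=McmcOptions(n_iter=2000, burn_in=500),
    )
    return run_experiment(config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_instance(rng, n=30, m=80, sigma2_e=1.0):
    """A small random SNP-regression instance with dosage genotypes."""
    from fastbayesa import EffectVariances, GenotypeMatrix, LocusInfo

    dosages = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    G = GenotypeMatrix(
        individuals=[f"i{i:03d}" for i in range(n)],
        loci=[LocusInfo(locus_id=f"l{j:03d}") for j in range(m)],
        dosages=dosages,
    )
    beta = rng.normal(0.0, 0.1, size=m)
    W = dosages.astype(float)
    y = 1.5 + W @ beta + rng.normal(0.0, np.sqrt(sigma2_e), size=n)
    X = np.ones((n, 1))
    D = EffectVariances(rng.uniform(0.01, 0.2, size=m))
    return y, X, G, D
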