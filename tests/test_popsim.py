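"""Simulator distributional checks: Haldane map, drift, equilibrium, scaling."""

import numpy as np
import pytest
from scipy import stats

from fastbayesa import (
    SimScenario,
    ValidationError,
    assign_qtl_effects,
    build_pedigree_generations,
    expected_me,
    load_scenario,
    meiosis_gamete,
    scenario_names,
    select_panel_and_qtl,
    simulate_phenotypes,
    simulate_scenario,
)
from fastbayesa.popsim import InsufficientQtlError, random_mating_generation
from tests.conftest import desk_scenario


class TestExpectedMe:
    @pytest.mark.parametrize(
        "chromosomes, expected", [(2, 241), (5, 543), (10, 1010)]
    )
    def test_reference_genome_lengths(self, chromosomes, expected):
        assert expected_me(500, chromosomes * 1.0) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            expected_me(0, 1.0)


class TestMeiosis:
    def _recomb_fraction(self, d, n_meioses, seed):
        rng = np.random.default_rng(seed)
        parent = np.array([[0, 0], [1, 1]], dtype=np.int8)
        positions = np.array([0.0, d])
        length = max(d, 1.0)
        diff = 0
        for _ in range(n_meioses):
            g = meiosis_gamete(parent, positions, length, rng)
            diff += int(g[0] != g[1])
        return diff / n_meioses

    def test_zero_distance_never_recombines(self):
        assert self._recomb_fraction(0.0, 2000, 1) == 0.0

    def test_haldane_fraction_at_tenth_morgan(self):
        n = 10**5
        r = self._recomb_fraction(0.1, n, 2)
        expected = 0.5 * (1 - np.exp(-0.2))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(r - expected) < 3 * se

    def test_distant_loci_approach_free_recombination(self):
        n = 10**5
        r = self._recomb_fraction(10.0, n, 3)
        se = np.sqrt(0.25 / n)
        assert abs(r - 0.5) < 3 * se

    def test_crossover_counts_poisson_and_gaps_exponential(self):
        # switch points on a long, densely mapped chromosome reveal the
        # crossover process: counts ~ Poisson(L), gaps ~ Exp(1)
        rng = np.random.default_rng(4)
        L, n_loci, n_meioses = 5.0, 2000, 20_000
        positions = (np.arange(n_loci) + 0.5) * L / n_loci
        parent = np.zeros((2, n_loci), dtype=np.int8)
        parent[1] = 1
        counts = np.empty(n_meioses, dtype=int)
        gaps = []
        for i in range(n_meioses):
            g = meiosis_gamete(parent, positions, L, rng)
            switches = np.flatnonzero(np.diff(g) != 0)
            counts[i] = switches.size
            if switches.size >= 2:
                gaps.append(np.diff(positions[switches]))
        # Poisson GOF on the counts (pool tail bins to keep expected >= 5)
        kmax = 12
        observed = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        probs = stats.poisson.pmf(np.arange(kmax), L)
        probs = np.append(probs, 1 - probs.sum())
        chi2 = ((observed - n_meioses * probs) ** 2 / (n_meioses * probs)).sum()
        assert stats.chi2.sf(chi2, kmax) > 0.01
        # KS on inter-crossover gaps: exponential Exp(1) gaps restricted to a
        # window of length L have density proportional to (L - g) e^{-g}
        # (the finite chromosome length biases which gaps are observable)
        gaps = np.concatenate(gaps)

        def windowed_exp_cdf(g):
            g = np.asarray(g, dtype=float)
            num = (L - 1) * (1 - np.exp(-g)) + g * np.exp(-g)
            den = (L - 1) * (1 - np.exp(-L)) + L * np.exp(-L)
            return num / den

        ks = stats.kstest(gaps, windowed_exp_cdf)
        assert ks.pvalue > 0.01


class TestDriftAndEquilibrium:
    def test_one_generation_drift_variance(self):
        # 300 unlinked loci (one per chromosome): Var(dp) = p(1-p)/(2N)
        rng = np.random.default_rng(5)
        sc = SimScenario(
            name="drift", effective_size=200, burnin_generations=0,
            expanded_size=300, n_sires=20, n_dams=100, dams_per_sire=5,
            pedigree_generations=6, chromosomes=300, loci_per_chrom=1,
            mutation_rate=0.0,
        )
        N = 200
        pool = (rng.random((N, 2, 300)) < 0.5).astype(np.int8)
        p0 = pool.sum(axis=(0, 1)) / (2 * N)
        off = random_mating_generation(pool, N, sc, rng)
        p1 = off.sum(axis=(0, 1)) / (2 * N)
        keep = (p0 > 0.05) & (p0 < 0.95)
        z2 = ((p1 - p0) ** 2 * 2 * N / (p0 * (1 - p0)))[keep]
        chi2 = z2.sum() * 1.0
        df = keep.sum()
        pval = stats.chi2.sf(chi2, df)
        assert 0.01 < pval

    def test_monomorphic_pool_stays_monomorphic_without_mutation(self):
        rng = np.random.default_rng(6)
        sc = SimScenario(
            name="mono", effective_size=30, burnin_generations=5,
            expanded_size=200, n_sires=20, n_dams=100, dams_per_sire=5,
            pedigree_generations=6, chromosomes=2, loci_per_chrom=50,
            mutation_rate=0.0, initial_allele_freq=1.0,
        )
        pool = np.ones((30, 2, 100), dtype=np.int8)
        for _ in range(5):
            pool = random_mating_generation(pool, 30, sc, rng)
        assert np.all(pool == 1)

    def test_heterozygosity_near_mutation_drift_equilibrium(self):
        # symmetric two-allele mutation: expected heterozygosity close to
        # the infinite-alleles value 4 Ne mu / (1 + 4 Ne mu) when 4 Ne mu
        # is small (documented approximation); time-averaged after burn-in
        rng = np.random.default_rng(7)
        ne, mu = 50, 2.5e-4
        sc = SimScenario(
            name="equilibrium", effective_size=ne, burnin_generations=0,
            expanded_size=200, n_sires=20, n_dams=100, dams_per_sire=5,
            pedigree_generations=6, chromosomes=8, loci_per_chrom=250,
            chrom_length=1.0, mutation_rate=mu, initial_allele_freq=0.5,
        )
        pool = (rng.random((ne, 2, 2000)) < 0.5).astype(np.int8)
        for _ in range(400):
            pool = random_mating_generation(pool, ne, sc, rng)
        hs = []
        for _ in range(400):
            pool = random_mating_generation(pool, ne, sc, rng)
            p = pool.sum(axis=(0, 1)) / (2 * ne)
            hs.append(np.mean(2 * p * (1 - p)))
        h = float(np.mean(hs))
        expected = 4 * ne * mu / (1 + 4 * ne * mu)
        assert abs(h - expected) / expected < 0.2


@pytest.fixture(scope="module")
def small_pedigree():
    sc = SimScenario(
        name="ped", effective_size=40, burnin_generations=0,
        expanded_size=60, expansion_generations=1,
        n_sires=4, n_dams=20, dams_per_sire=5, offspring_per_dam=(1, 1),
        pedigree_generations=3, validation_generations=2,
        chromosomes=2, loci_per_chrom=50, mutation_rate=0.0,
    )
    rng = np.random.default_rng(8)
    founders = (rng.random((24, 2, 100)) < 0.5).astype(np.int8)
    ped, gens = build_pedigree_generations(sc, founders, rng)
    return sc, ped, gens


class TestPedigree:
    def test_generation_sizes_follow_the_design(self, small_pedigree):
        sc, ped, gens = small_pedigree
        assert len(gens[0][0]) == sc.n_founders == 24
        for ids, _ in gens[1:]:
            assert len(ids) == sc.offspring_per_generation == 40
        assert len(ped.frame) == 24 + 3 * 40

    def test_offspring_sex_counts_exact(self, small_pedigree):
        _, ped, _ = small_pedigree
        per_gen = ped.frame[ped.frame["generation"] > 0].groupby(
            ["generation", "sex"]
        ).size()
        assert set(per_gen.values) == {20}

    def test_offspring_alleles_trace_to_recorded_parents(self, small_pedigree):
        # without mutation, each haplotype must be a mosaic of its parent's
        _, ped, gens = small_pedigree
        lookup = {}
        for ids, genomes in gens:
            for k, ind in enumerate(ids):
                lookup[ind] = genomes[k]
        records = ped.frame[ped.frame["generation"] > 0]
        for row in records.itertuples(index=False):
            child = lookup[row.individual_id]
            sire, dam = lookup[row.sire_id], lookup[row.dam_id]
            assert np.all((child[0] == sire[0]) | (child[0] == sire[1]))
            assert np.all((child[1] == dam[0]) | (child[1] == dam[1]))

    def test_training_size_formula_matches_reference_design(self):
        for name, expected in [("B1", 620), ("A1", 1020), ("B5", 2220)]:
            assert load_scenario(name).training_size == expected


class TestPanelAndQtl:
    def test_inclusive_maf_threshold(self):
        sc = desk_scenario(n_qtl=0)
        freqs = np.array([0.01, 0.05, 0.5])
        snp, qtl = select_panel_and_qtl(freqs, np.array([], dtype=int), sc,
                                        np.random.default_rng(0))
        assert snp.tolist() == [1, 2]
        assert qtl.size == 0

    def test_insufficient_candidates_raise(self):
        sc = desk_scenario(n_qtl=5)
        freqs = np.full(100, 0.001)  # everything below the QTL MAF cutoff
        with pytest.raises(InsufficientQtlError, match="candidates"):
            select_panel_and_qtl(freqs, np.arange(10), sc,
                                 np.random.default_rng(0))

    def test_const_mode_equal_variance_contributions(self):
        sc = desk_scenario(qtl_variance_mode="const", n_qtl=4)
        rng = np.random.default_rng(9)
        truth = assign_qtl_effects(np.arange(4), np.full(4, 0.5), sc, rng)
        np.testing.assert_allclose(np.abs(truth.effects), np.sqrt(0.25 / 0.5))
        np.testing.assert_allclose(truth.variance_contributions, 0.25)

    @pytest.mark.parametrize("mode", ["hetero", "const"])
    def test_scaling_hits_target_variance_exactly(self, mode):
        sc = desk_scenario(qtl_variance_mode=mode, n_qtl=50)
        rng = np.random.default_rng(10)
        freqs = rng.uniform(0.05, 0.95, size=50)
        truth = assign_qtl_effects(np.arange(50), freqs, sc, rng)
        assert truth.variance_contributions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_hetero_effect_sizes_have_gamma_dispersion(self):
        # scale-free check: |a| / mean(|a|) keeps the Gamma(shape) coefficient
        # of variation 1/sqrt(shape) regardless of the common rescaling
        sc = desk_scenario(qtl_variance_mode="hetero", n_qtl=20000,
                           qtl_me_multiplier=None)
        rng = np.random.default_rng(11)
        freqs = np.full(20000, 0.5)
        truth = assign_qtl_effects(np.arange(20000), freqs, sc, rng)
        mags = np.abs(truth.effects)
        cv = mags.std(ddof=1) / mags.mean()
        assert cv == pytest.approx(1.0 / np.sqrt(sc.gamma_shape), rel=0.05)
        # signs unbiased
        assert abs(np.mean(np.sign(truth.effects))) < 3 / np.sqrt(20000)


class TestPhenotypes:
    def test_residual_variance_from_heritability(self):
        assert desk_scenario(heritability=0.5).residual_variance == pytest.approx(1.0)
        assert desk_scenario(heritability=0.1).residual_variance == pytest.approx(9.0)

    def test_regression_of_phenotype_on_tbv_is_unit_slope(self):
        import pandas as pd

        rng = np.random.default_rng(12)
        sc = desk_scenario(heritability=0.5)
        tbv = pd.Series(rng.normal(0, 1, size=10**4),
                        index=[f"i{k}" for k in range(10**4)])
        pheno = simulate_phenotypes(tbv, sc, rng)
        x = tbv.to_numpy()
        y = pheno.values
        slope = np.cov(x, y)[0, 1] / np.var(x, ddof=1)
        se = np.sqrt(sc.residual_variance / (np.var(x, ddof=1) * x.size))
        assert abs(slope - 1.0) < 3 * se


class TestSimulateScenario:
    def test_same_seed_is_bitwise_identical(self):
        sc = desk_scenario(burnin_generations=20, loci_per_chrom=100, seed=42)
        a = simulate_scenario(sc)
        b = simulate_scenario(sc)
        np.testing.assert_array_equal(a.genotypes[0].dosages, b.genotypes[0].dosages)
        np.testing.assert_array_equal(a.truth.effects, b.truth.effects)
        np.testing.assert_array_equal(a.phenotypes.values, b.phenotypes.values)

    def test_no_qtl_means_pure_noise_trait(self):
        sc = desk_scenario(burnin_generations=20, loci_per_chrom=100,
                           n_qtl=0, seed=43)
        ds = simulate_scenario(sc)
        assert np.all(ds.tbv.to_numpy() == 0.0)
        assert ds.phenotypes.values.std() > 0

    def test_realized_training_genetic_variance_near_target(self, desk_datasets):
        realized = [
            ds.tbv_of(ds.training_genotypes().individuals).var(ddof=1)
            for ds in desk_datasets
        ]
        assert abs(np.mean(realized) - 1.0) < 0.15

    def test_phenotype_residuals_have_the_designed_variance(self, desk_datasets):
        resid = np.concatenate(
            [
                ds.phenotypes.aligned_to(ds.training_genotypes()).values
                - ds.tbv_of(ds.training_genotypes().individuals)
                for ds in desk_datasets
            ]
        )
        target = desk_datasets[0].scenario.residual_variance
        se = target * np.sqrt(2.0 / resid.size)
        assert abs(resid.var(ddof=1) - target) < 4 * se

    def test_dosage_column_means_match_stored_frequencies(self, desk_datasets):
        g = desk_datasets[0].genotypes[1]
        np.testing.assert_allclose(
            g.dosages.mean(axis=0) / 2.0, g.allele_freqs(), atol=1e-12
        )

    def test_shipped_scenarios_load(self):
        assert set(scenario_names()) >= {"A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4", "B5"}
        a1 = load_scenario("A1")
        assert a1.me == 241 and a1.resolved_n_qtl == 24
        b4 = load_scenario("B4", heritability=0.1)
        assert b4.me == 1010 and b4.heritability == 0.1
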