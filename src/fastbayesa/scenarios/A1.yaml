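name: A1
effective_size: 500
burnin_generations: 1000
expanded_size: 1000
expansion_generations: 5
n_sires: 20
n_dams: 200
dams_per_sire: 10
offspring_per_dam:
- 1
- 1
pedigree_generations: 7
validation_generations: 5
chromosomes: 2
chrom_length: 1.0
loci_per_chrom: 2000
mutation_rate: 2.5e-05
initial_allele_freq: 0.5
maf_min_snp: 0.05
maf_min_qtl: 0.05
n_qtl: null
qtl_me_multiplier: 0.1
qtl_candidate_multiplier: 2.0
qtl_variance_mode: hetero
gamma_shape: 0.4
gamma_scale: 1.66
qtl_in_panel: false
heritability: 0.5
genetic_variance_target: 1.0
seed: 0
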