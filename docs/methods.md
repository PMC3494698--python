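# Methods

## Model

Phenotypes of `n` training individuals follow the SNP regression

```
y = X b + W beta + e,      e ~ N(0, sigma2_e I),
```

where `W` is the n x m matrix of counted-allele dosages (0/1/2), centered
column-wise by twice the allele frequency by default, and `beta` the allele
substitution effects.  Under GBLUP every effect shares one variance
`sigma2_g / sum_j 2 p_j (1 - p_j)`; under BayesA each SNP has its own
variance `sigma2_j` with a scaled inverse chi-square prior
`ScaledInvChi2(nu, S)`, making the marginal effect prior a scaled t and the
shrinkage effect-size dependent.

The model is equivalent to an animal model with breeding values
`g = W beta` and covariance `V_g = W D W'`, `D = diag(sigma2_j)`.  All
solvers here work in the individual dimension: with
`V = V_g + sigma2_e I`,

```
b_hat    = (X' V^-1 X)^-1 X' V^-1 y          (GLS)
g_hat    = V_g V^-1 (y - X b_hat)            (BLUP)
beta_hat = D W' V^-1 (y - X b_hat)           (back-solving)
```

so the cost per solve is one dense factorization of an n x n matrix,
independent of the number of markers.  `snp_blup_direct` solves the same
problem in marker dimension (Henderson equations with `W'W + sigma2_e
D^-1`) and is used purely as an independent oracle in the tests.

## The EM algorithm

Per-SNP variances are treated as missing data.  Given current effects, the
conditional posterior of `sigma2_j` is `ScaledInvChi2(nu + 1, (nu S +
beta_j^2)/(nu + 1))`, and the E-step stores exactly that scale — the value
whose reciprocal is `E[1/sigma2_j | beta_j]`, which is what the quadratic
penalty of the next M-step needs.  The M-step jointly re-estimates `(b,
beta)` by the animal-model BLUP plus back-solving above.  The iteration
ascends the marginalized objective

```
-||y - X b - W beta||^2 / (2 sigma2_e)  -  (nu + 1)/2 * sum_j log(nu S + beta_j^2)
```

(Gaussian log-likelihood plus scaled-t log prior, constants dropped) and
converges to a joint posterior mode of the SNP effects.  Because the
variances are initialized at the GBLUP common variance, iteration 1
reproduces GBLUP exactly; accuracy can only be studied relative to that
baseline.  Monotone ascent, the E-step/M-step fixed point and numerical
stationarity of the objective at the returned solution are asserted in the
test-suite.

Defaults and their reasons:

- `nu = 4.012`: the customary low-information choice for marker-effect
  variances in this literature; must exceed 2 so the prior mean exists.
- `S = (nu - 2)/nu * sigma2_g / sum_j 2 p_j q_j`: sets the prior *mean*
  effect variance equal to the GBLUP common variance, so the degenerate
  prior (`nu -> inf`) recovers GBLUP exactly.
- convergence: relative squared change of the effect vector,
  `sum (beta_new - beta_old)^2 / max(sum beta_old^2, 1e-30) < tol`, default
  `tol = 1e-8`, `max_iter = 100`.  Validation accuracy stabilizes well
  before this criterion triggers; the tight default costs a few extra
  cheap iterations.  Non-convergence returns a flagged result plus a
  warning rather than raising.
- effect-variance floor `1e-12 x` GBLUP variance: numerical guard only, so
  the marker-dimension oracle (which needs `D^-1`) stays defined; the
  back-solving path never inverts `D`.
- `sigma2_e` is held at the supplied value by default.
  `update_residual=True` switches on the per-iteration mean-square-error
  update `sigma2_e = ||y - X b_hat - W beta_hat||^2 / n`, which is the
  sigma2_e maximization step of the joint-mode objective (see Limitations).

## Reference Gibbs samplers

`bayesa_gibbs` / `bayesb_gibbs` are single-site samplers used as
comparators: effects one at a time from their Normal full conditionals,
per-SNP variances from `ScaledInvChi2(nu + 1, (nu S + beta_j^2)/(nu + 1))`,
`sigma2_e` from its scaled inverse chi-square full conditional (prior df
`nu`, prior mean at the supplied residual variance), fixed effects
single-site with flat priors.  BayesB adds an inclusion indicator per SNP
drawn with the effect integrated out against the current `sigma2_j`
(retained for excluded SNPs), a plain Gibbs step on (indicator, effect,
variance); with `pi_zero = 0` the BayesA code path is followed exactly.
For BayesB the per-included-SNP prior scale is inflated by `1/(1 - pi)` so
the non-zero fraction of markers still accounts for `sigma2_g` in
expectation.  Chains are seeded and bitwise reproducible.  Defaults
`n_iter = 10,000`, `burn_in = 1,000`; the shipped experiment harness scales
these down for desk runs.  Posterior correctness is checked against a
two-dimensional quadrature of the exact posterior on a one-SNP instance.

## Simulator

`popsim` emulates a livestock-style pedigreed population:

1. a historical population of effective size `Ne` random-mates for
   `burnin_generations` starting from allele frequency 0.5 in
   Hardy-Weinberg proportions, with symmetric allele-flipping mutation at
   `mutation_rate` per meiosis per locus, then grows linearly to
   `expanded_size` over `expansion_generations`;
2. meiosis draws `Poisson(length)` crossovers per chromosome, positions
   uniform, no interference, so recombination follows the Haldane map
   `r = (1 - exp(-2d))/2` (verified empirically to 3 Monte-Carlo SE);
3. founders (`n_sires + n_dams`) are sampled from the expanded generation;
   each sire mates `dams_per_sire` random dams, each dam leaves a fixed
   number of male and female offspring; next-generation parents are drawn
   from the offspring, for `pedigree_generations` discrete generations;
4. the SNP panel keeps non-candidate loci with MAF >= `maf_min_snp`
   (inclusive) in the founder cohort; QTL are drawn from pre-placed
   candidate loci (`qtl_candidate_multiplier x n_qtl` of them) with MAF >=
   `maf_min_qtl`, and are excluded from the panel (configurable);
5. QTL effects are gamma-distributed magnitudes with random signs
   ("hetero") or equal-variance `+/- sqrt(c / 2 p q)` ("const"), rescaled
   by one common factor so `sum 2 p q a^2` equals the target genetic
   variance exactly in the founder cohort;
6. phenotype = true breeding value + `N(0, sigma2_g (1 - h2)/h2)` noise.

The reporting quantity `Me = 2 Ne L / ln(4 Ne L)` (effective number of
independently segregating segments) reproduces 241 / 543 / 1,010 for 2, 5
and 10 chromosomes of 1 Morgan at `Ne = 500`, and QTL counts are specified
as multiples of it.

Several constants of the emulated design are reconstructions, since they
are pinned only indirectly: `Ne = 500` and 1-Morgan chromosomes (they
reproduce the Me triplet above), a 20-sire x 200-dam x (1 + 1)-offspring
pedigree (training sizes 620 / 1,020 / 2,220 for 1 / 2 / 5 offspring
generations), burn-in 1,000 generations, 2,000 initial loci per chromosome,
mutation rate 2.5e-5, MAF cutoffs 0.05, gamma shape 0.4 / scale 1.66,
candidate multiplier 2.  The expansion (to 1,000 over 5 generations) is the
package's own choice.  Every value is a visible `SimScenario` field and is
serialized into the shipped YAML scenario library (A1-A4, B1-B5).

What the simulator does *not* emulate: selection (parents are random),
overlapping generations, genotyping error or missingness, non-additive
gene action, and sequence-scale marker density.  Passing tests therefore
demonstrate correctness of the estimation machinery under an idealized
additive architecture, not performance on real livestock data.

### Desk-scale profile

The test-suite exercises the full pipeline on a reduced profile chosen once
for turnaround: `Ne = 100`, burn-in 200 generations (= 2 Ne, the same
drift regime as the full design), `mutation_rate = 1.25e-4` (preserving
`4 Ne mu = 0.05`), 2 chromosomes x 400 initial loci, 20 sires x 100 dams,
training = 520 individuals over 3 generations, `0.1 Me = 6` QTL,
`h2 = 0.5`, 10 paired replicates, Gibbs chains of 2,000 iterations.
Method comparisons at this scale reproduce the qualitative accuracy
ordering BayesB > fastBayesA ~ BayesA > GBLUP.

## Numerical choices

- `V` is factorized by dense Cholesky; on failure a jitter of
  `1e-8 trace(V)/n` is added once, with a loud log message.
- Centering by `2 p_j` is the default everywhere (better conditioning; GEBV
  contrasts are provably invariant, which the suite asserts).  Validation
  panels are centered with *training* frequencies.
- Fixed-effect designs must be full column rank; rank deficiency is
  reported with the offending columns.  Experiments use an intercept only.
- Degenerate inputs: zero markers fall back to a fixed-effect-only fit;
  monomorphic panels and non-positive variances raise validation errors;
  per-SNP variances reaching zero simply zero the corresponding effect.

## Known limitations

- The EM finds a *local* joint mode; with multimodal posteriors different
  starting points could end elsewhere.  The GBLUP start guarantees the fit
  never predicts worse than GBLUP at iteration 1, and the stationarity
  check guards against premature stops, but no global search is attempted.
- Dispersion of the mode-based GEBV: across the scales we simulate, the
  regression of TBV on GEBV for the EM fit sits slightly *above* the
  BayesA posterior-mean fit (the mode zeroes many small effects, deflating
  GEBV variance), so the EM's dispersion bias is not uniformly worse than
  BayesA's — where the balance falls depends on the genetic architecture
  and data size, and reports of the opposite ordering exist for other
  simulation designs.  The suite prints both slopes for the shipped desk
  profile.
- The mean-square-error residual update (`update_residual=True`) is the
  exact `sigma2_e` step of the joint-mode objective, but because the mode
  overfits the training data it systematically lowers `sigma2_e` below the
  generating value in our simulations, *increasing* GEBV dispersion.  Use
  it for exploration, not as a default.
- The dense individual-dimension solver targets n up to a few thousand;
  larger training sets need iterative solvers that are out of scope here.
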