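"""Validation metrics and replicate orchestration.

Accuracy is the Pearson correlation of true breeding values with GEBV;
dispersion bias is the regression coefficient of TBV on GEBV (1 means the
GEBV are neither over- nor under-dispersed).  ``run_experiment`` repeats
the whole pipeline — simulate, train every requested method on the same
replicate, predict each validation generation — so method comparisons are
paired at the replicate level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .blup_engine import gblup_fit, predict_gebv
from .fastbayesa_em import BayesAPrior, EMOptions, fastbayesa_fit, scale_from_genetic_variance
from .genomic_data import ValidationError, VarianceComponents
from .mcmc_reference import McmcOptions, bayesa_gibbs, bayesb_gibbs
from .popsim import SimScenario, SimulatedDataset, simulate_scenario

__all__ = [
    "UndefinedMetricError",
    "EvalReport",
    "ExperimentConfig",
    "accuracy",
    "bias_slope",
    "run_experiment",
    "em_iteration_accuracy_curve",
    "KNOWN_METHODS",
]

logger = logging.getLogger("fastbayesa")

KNOWN_METHODS = ("gblup", "fastbayesa", "bayesa", "bayesb")


class UndefinedMetricError(ValidationError):
    """Metric undefined (too few points or zero variance)."""


def accuracy(tbv: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation of TBV with GEBV."""
    tbv = np.asarray(tbv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if tbv.shape != gebv.shape or tbv.size < 3:
        raise UndefinedMetricError("need two equal-length vectors of >= 3 values")
    if np.var(tbv) == 0 or np.var(gebv) == 0:
        raise UndefinedMetricError("zero variance: correlation undefined")
    return float(np.corrcoef(tbv, gebv)[0, 1])


def bias_slope(tbv: np.ndarray, gebv: np.ndarray) -> float:
    """Regression coefficient of TBV on GEBV: cov(tbv, gebv) / var(gebv)."""
    tbv = np.asarray(tbv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if tbv.shape != gebv.shape or tbv.size < 3:
        raise UndefinedMetricError("need two equal-length vectors of >= 3 values")
    vg = np.var(gebv)
    if vg == 0:
        raise UndefinedMetricError("zero GEBV variance: slope undefined")
    return float(np.cov(tbv, gebv)[0, 1] / np.cov(gebv)[()])


@dataclass
class ExperimentConfig:
    """One experiment: a scenario, a method set and a replicate count."""

    scenario: SimScenario
    methods: tuple[str, ...] = ("gblup", "fastbayesa")
    replicates: int = 10
    seed_base: int = 1000
    em_options: EMOptions = field(default_factory=EMOptions)
    prior_df: float = 4.012
    mcmc: McmcOptions = field(default_factory=McmcOptions)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValidationError("need at least one replicate")
        unknown = set(self.methods) - set(KNOWN_METHODS)
        if unknown:
            raise ValidationError(f"unknown methods: {sorted(unknown)}")


@dataclass
class EvalReport:
    """Per-replicate metrics plus across-replicate summaries.

    ``per_replicate`` columns: method, generation (1 = first validation
    generation), replicate, accuracy, slope.
    """

    per_replicate: pd.DataFrame
    failed_replicates: int = 0

    def summary(self) -> pd.DataFrame:
        """Mean and standard error (sd / sqrt(n)) across replicates."""
        g = self.per_replicate.groupby(["method", "generation"])
        out = g.agg(
            accuracy=("accuracy", "mean"),
            accuracy_se=("accuracy", lambda v: v.std(ddof=1) / np.sqrt(len(v))),
            slope=("slope", "mean"),
            slope_se=("slope", lambda v: v.std(ddof=1) / np.sqrt(len(v))),
            n=("accuracy", "size"),
        )
        return out.reset_index()

    def first_generation_means(self) -> pd.DataFrame:
        s = self.summary()
        return s[s["generation"] == 1].set_index("method")


def _fit_and_predict(
    method: str,
    dataset: SimulatedDataset,
    config: ExperimentConfig,
    replicate_seed: int,
) -> np.ndarray:
    """Train ``method`` on the replicate's training set; return SNP effects."""
    y, X, G = dataset.training_data()
    vc = VarianceComponents(
        genetic_variance=dataset.scenario.genetic_variance_target,
        residual_variance=dataset.scenario.residual_variance,
    )
    freqs = G.allele_freqs()
    if method == "gblup":
        return gblup_fit(y, X, G, vc).snp_effects
    if method == "fastbayesa":
        prior = BayesAPrior(
            df=config.prior_df,
            scale=scale_from_genetic_variance(config.prior_df, vc, freqs),
        )
        return fastbayesa_fit(y, X, G, vc, prior=prior, options=config.em_options).snp_effects
    prior = BayesAPrior(
        df=config.prior_df,
        scale=scale_from_genetic_variance(config.prior_df, vc, freqs),
    )
    if method == "bayesa":
        opts = McmcOptions(
            n_iter=config.mcmc.n_iter, burn_in=config.mcmc.burn_in,
            seed=replicate_seed, pi_zero=0.0,
        )
        return bayesa_gibbs(y, X, G, prior, vc, opts).mean_effects
    if method == "bayesb":
        # prior zero-proportion: 1 - (number of QTL / number of SNPs); the
        # per-included-SNP variance scale is inflated by 1/(1 - pi) so the
        # non-zero fraction of markers still explains sigma2_g in expectation
        n_qtl = dataset.truth.qtl_indices.size
        pi_zero = max(0.0, 1.0 - n_qtl / G.n_loci)
        prior_b = BayesAPrior(df=prior.df,
                              scale=prior.scale / max(1.0 - pi_zero, 1e-12))
        opts = McmcOptions(
            n_iter=config.mcmc.n_iter, burn_in=config.mcmc.burn_in,
            seed=replicate_seed, pi_zero=pi_zero,
        )
        return bayesb_gibbs(y, X, G, prior_b, vc, opts).mean_effects
    raise ValidationError(f"unknown method {method!r}")


def run_experiment(config: ExperimentConfig) -> EvalReport:
    """Simulate ``replicates`` datasets and evaluate every method on each.

    Replicate r uses seed ``seed_base + r``; all methods see the same data.
    Failed replicates are logged and dropped; more than 20% failing is an
    error.
    """
    from dataclasses import replace as dc_replace

    records = []
    failures = 0
    for r in range(config.replicates):
        seed = config.seed_base + r
        try:
            dataset = simulate_scenario(dc_replace(config.scenario, seed=seed))
            train_freqs = dataset.training_genotypes().allele_freqs()
            for method in config.methods:
                effects = _fit_and_predict(method, dataset, config, seed)
                for gen in range(1, dataset.scenario.validation_generations + 1):
                    G_val = dataset.validation_genotypes(gen)
                    gebv = predict_gebv(G_val, effects, centering_freqs=train_freqs)
                    tbv = dataset.tbv_of(G_val.individuals)
                    records.append(
                        {
                            "method": method,
                            "generation": gen,
                            "replicate": r,
                            "accuracy": accuracy(tbv, gebv),
                            "slope": bias_slope(tbv, gebv),
                        }
                    )
        except Exception:  # noqa: BLE001 - per-replicate isolation is the point
            failures += 1
            logger.exception("replicate %d failed, excluding it", r)
    if failures > 0.2 * config.replicates:
        raise ValidationError(
            f"{failures}/{config.replicates} replicates failed; aborting"
        )
    return EvalReport(per_replicate=pd.DataFrame(records), failed_replicates=failures)


def em_iteration_accuracy_curve(
    config: ExperimentConfig, replicate_seed: int
) -> pd.DataFrame:
    """First-validation-generation GEBV accuracy at every EM iteration.

    The first entry is the GBLUP accuracy by construction (the EM starts at
    the GBLUP variance).  Returns columns iteration, accuracy.
    """
    from dataclasses import replace as dc_replace

    dataset = simulate_scenario(dc_replace(config.scenario, seed=replicate_seed))
    y, X, G = dataset.training_data()
    vc = VarianceComponents(
        genetic_variance=dataset.scenario.genetic_variance_target,
        residual_variance=dataset.scenario.residual_variance,
    )
    G_val = dataset.validation_genotypes(1)
    tbv = dataset.tbv_of(G_val.individuals)
    result = fastbayesa_fit(
        y, X, G, vc,
        prior=BayesAPrior(
            df=config.prior_df,
            scale=scale_from_genetic_variance(config.prior_df, vc, G.allele_freqs()),
        ),
        options=config.em_options,
        validation=(G_val, tbv),
    )
    return pd.DataFrame(
        {
            "iteration": [rec.iteration for rec in result.trace.records],
            "accuracy": [rec.validation_accuracy for rec in result.trace.records],
        }
    )
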