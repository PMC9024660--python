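"""Simulation studies validating the estimation machinery.

Replicated experiments on synthetic cohorts: type-I error and parameter
recovery of the module-level mixed model, false-discovery calibration of
the BH-corrected model families, and planted-partition recovery of the
consensus clustering. These run at deliberately reduced problem sizes so a
full calibration study completes in minutes on one CPU; sizes are
arguments, not constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import association as assoc
from . import community
from .synthetic import (
    CohortConfig,
    cohort_frame,
    generate_cohort,
    generate_connectome,
    null_metric_table,
    plant_effect,
    planted_partition_labels,
)


def _seed_stream(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % (2**31)) for c in np.random.SeedSequence(seed).spawn(n)]


def association_replicate(
    seed: int,
    beta: float,
    n_subjects: int = 30,
    n_nodes: int = 40,
    n_modules: int = 4,
    beta_sex: float = 0.0,
    trait: str = "ve",
    **config_kwargs,
) -> assoc.AssociationResult:
    """One synthetic cohort -> planted metric table -> module-model fit.

    The metric baseline is flat (the model has an intercept), so the fit
    isolates the generative mixed-model structure; the target module is the
    first planted block.
    """
    cfg = CohortConfig(
        n_subjects=n_subjects,
        n_nodes=n_nodes,
        n_modules_planted=n_modules,
        planted_beta=beta,
        planted_beta_sex=beta_sex,
        seed=seed,
        **config_kwargs,
    )
    records = generate_cohort(cfg)
    table = plant_effect(null_metric_table(records, cfg), records, cfg, seed=seed + 1)
    nodes = np.flatnonzero(planted_partition_labels(cfg) == cfg.target_module)
    long = assoc.build_long_table(
        table, cohort_frame(records), 1.0, nodes, cfg.target_metric, trait
    )
    spec = assoc.ModelSpec(cfg.target_metric, trait, 1.0, cfg.target_module)
    return assoc.fit_module_model(long, spec)


@dataclass
class CalibrationReport:
    """Outcome of a replicated simulation experiment."""

    n_replicates: int
    type_i_error: float | None = None
    mean_beta: float | None = None
    ci_coverage: float | None = None
    empirical_fdr: float | None = None


def type_i_error(
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    **replicate_kwargs,
) -> CalibrationReport:
    """Rejection rate of the trait fixed effect under the simulator null."""
    rejections = 0
    for s in _seed_stream(seed, n_replicates):
        fit = association_replicate(s, beta=0.0, **replicate_kwargs)
        rejections += fit.beta_trait.p < alpha
    return CalibrationReport(n_replicates, type_i_error=rejections / n_replicates)


def beta_recovery(
    beta: float = 3.2,
    n_replicates: int = 50,
    seed: int = 0,
    **replicate_kwargs,
) -> CalibrationReport:
    """Mean recovered slope and 95% CI coverage for a planted effect."""
    estimates, covered = [], 0
    for s in _seed_stream(seed, n_replicates):
        fit = association_replicate(s, beta=beta, **replicate_kwargs)
        estimates.append(fit.beta_trait.estimate)
        covered += fit.beta_trait.ci_low <= beta <= fit.beta_trait.ci_high
    return CalibrationReport(
        n_replicates,
        mean_beta=float(np.mean(estimates)),
        ci_coverage=covered / n_replicates,
    )


def fdr_calibration(
    n_replicates: int = 500,
    seed: int = 0,
    q: float = 0.05,
    n_subjects: int = 12,
    n_nodes: int = 8,
    n_modules: int = 2,
    metric_names: tuple[str, ...] = ("degree", "betweenness"),
) -> CalibrationReport:
    """Empirical FDR of BH-corrected module x metric families under the null.

    Each replicate fits one model per (module, metric) on a null cohort
    (no planted effect anywhere), BH-corrects the family of trait p-values,
    and counts discoveries at the given q; every discovery is false, so the
    per-replicate false-discovery proportion is 1 if anything is declared.
    """
    fdp = []
    for s in _seed_stream(seed, n_replicates):
        cfg = CohortConfig(
            n_subjects=n_subjects,
            n_nodes=n_nodes,
            n_modules_planted=n_modules,
            planted_beta=0.0,
            seed=s,
        )
        records = generate_cohort(cfg)
        table = plant_effect(
            null_metric_table(records, cfg, metrics=metric_names),
            records, cfg, seed=s + 1,
        )
        cohort = cohort_frame(records)
        labels = planted_partition_labels(cfg)
        pvals = []
        for module in range(n_modules):
            nodes = np.flatnonzero(labels == module)
            for metric in metric_names:
                long = assoc.build_long_table(table, cohort, 1.0, nodes, metric, "ve")
                fit = assoc.fit_module_model(
                    long, assoc.ModelSpec(metric, "ve", 1.0, module)
                )
                pvals.append(fit.beta_trait.p)
        discoveries = int((assoc.fdr_correct(pvals) < q).sum())
        fdp.append(1.0 if discoveries > 0 else 0.0)
    return CalibrationReport(n_replicates, empirical_fdr=float(np.mean(fdp)))


def consensus_recovery_ari(
    n_subjects: int = 25,
    n_nodes: int = 60,
    n_modules: int = 4,
    p_in: float = 0.4,
    p_out: float = 0.05,
    gamma: float = 1.0,
    reps: int = 50,
    seed: int = 0,
) -> float:
    """Adjusted Rand index of the consensus partition vs the planted truth."""
    from sklearn.metrics import adjusted_rand_score

    cfg = CohortConfig(
        n_subjects=n_subjects,
        n_nodes=n_nodes,
        n_modules_planted=n_modules,
        p_in=p_in,
        p_out=p_out,
        seed=seed,
    )
    records = generate_cohort(cfg)
    seeds = _seed_stream(seed + 1, n_subjects)
    parts = [
        community.louvain_finetune(
            generate_connectome(cfg, rec).values, gamma=gamma, seed=s
        )
        for rec, s in zip(records, seeds)
    ]
    cons = community.consensus_partition(
        community.agreement(parts), reps=reps, seed=seed + 2
    )
    return float(adjusted_rand_score(planted_partition_labels(cfg), cons.labels))


def sweep_monotonicity(
    n_subjects: int = 10,
    n_nodes: int = 60,
    n_modules: int = 4,
    gammas: tuple[float, ...] = (0.3, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Mean modularity and module count across a gamma sweep on a cohort."""
    cfg = CohortConfig(
        n_subjects=n_subjects, n_nodes=n_nodes, n_modules_planted=n_modules, seed=seed
    )
    records = generate_cohort(cfg)
    rows = []
    for rec, s in zip(records, _seed_stream(seed + 1, n_subjects)):
        adj = generate_connectome(cfg, rec).values
        for part in community.gamma_sweep(adj, gammas=gammas, seed=s):
            rows.append(
                {"subject_id": rec.subject_id, "gamma": part.gamma,
                 "q": part.q, "n_modules": part.n_modules}
            )
    return (
        pd.DataFrame(rows)
        .groupby("gamma", as_index=False)
        .agg(mean_q=("q", "mean"), mean_modules=("n_modules", "mean"))
    )
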