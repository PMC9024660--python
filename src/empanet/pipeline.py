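"""Configuration-driven end-to-end runner.

Stages: cohort (simulate or load) -> connectomes -> per-subject gamma sweep
-> group consensus modules per gamma -> nodal metrics -> behavioral scoring
-> mixed-effects association with FDR and cross-gamma models. Every stage
writes its outputs as delimited text under the run directory, a JSON
manifest records the configuration echo, seeds, package versions and stage
timings, and any stage failure aborts with the stage name while preserving
partial outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import behavior, community, metrics
from ._version import __version__
from .connectome import (
    Connectome,
    fisher_z_connectome,
    load_connectome,
    load_timeseries,
    proportional_threshold,
    save_connectome,
)
from .synthetic import (
    CohortConfig,
    cohort_frame,
    generate_cohort,
    generate_connectome,
    plant_effect,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one run needs; exactly one input source must be set.

    Either ``simulator`` (a :class:`CohortConfig`) or the real-input paths
    (``subject_table`` plus one of ``timeseries_dir`` / ``connectome_dir``).
    """

    out_dir: str = "empanet_run"
    simulator: CohortConfig | None = None
    subject_table: str | None = None
    timeseries_dir: str | None = None
    connectome_dir: str | None = None
    connectome_mode: str = "adjacency"  # simulator: adjacency | timeseries
    density: float = 0.10
    gammas: tuple[float, ...] = community.DEFAULT_GAMMA_GRID
    consensus_reps: int = 1000
    module_screen_nulls: int = 100
    fdr_q: float = 0.05
    traits: tuple[str, ...] = ("ve", "iu")
    metric_names: tuple[str, ...] = metrics.METRIC_NAMES
    seed: int = 0
    save_connectomes: bool = True

    def __post_init__(self) -> None:
        simulated = self.simulator is not None
        real = self.subject_table is not None and (
            self.timeseries_dir is not None or self.connectome_dir is not None
        )
        if simulated == real:
            raise ValueError(
                "supply exactly one of: a simulator config, or a subject table "
                "with time-series/connectome paths"
            )

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["gammas"] = list(self.gammas)
        raw["traits"] = list(self.traits)
        raw["metric_names"] = list(self.metric_names)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw.get("simulator") is not None:
            sim = dict(raw["simulator"])
            for key in ("group_proportions", "age_range"):
                if sim.get(key) is not None:
                    sim[key] = tuple(sim[key])
            raw["simulator"] = CohortConfig(**sim)
        for key in ("gammas", "traits", "metric_names"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def demo_config(out_dir: str = "empanet_demo", seed: int = 0) -> RunConfig:
    """Small planted-effect demonstration run (minutes on one CPU)."""
    sim = CohortConfig(
        n_subjects=20,
        n_nodes=60,
        n_modules_planted=4,
        planted_beta=3.2,
        n_groups=2,
        group_proportions=(1, 1),
        seed=seed,
    )
    return RunConfig(
        out_dir=out_dir,
        simulator=sim,
        gammas=(0.5, 1.0, 1.5),
        consensus_reps=50,
        module_screen_nulls=50,
        seed=seed,
    )


@dataclass
class RunResult:
    """In-memory bundle of everything a run produced."""

    cohort: pd.DataFrame
    adjacencies: dict[str, np.ndarray]
    partitions: dict[float, dict[str, community.Partition]]
    q_table: pd.DataFrame
    consensus: dict[float, community.Partition]
    module_keep: dict[float, pd.DataFrame]
    metric_table: pd.DataFrame
    descriptives: behavior.BehavioralDescriptives
    modularity_correlations: dict[str, dict]
    results: pd.DataFrame
    blups: pd.DataFrame
    cross_gamma: pd.DataFrame
    out_dir: Path


def _stage(name: str, manifest: dict):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            self.t0 = time.time()
            return self

        def __exit__(self, exc_type, exc, tb):
            elapsed = round(time.time() - self.t0, 2)
            manifest["stages"][name] = {
                "seconds": elapsed,
                "status": "failed" if exc else "ok",
            }
            if exc:
                logger.error("stage %s failed after %.1fs: %s", name, elapsed, exc)
                raise StageError(name, exc) from exc
            logger.info("stage %s: done in %.1fs", name, elapsed)
            return False

    return _Ctx()


def _load_cohort(config: RunConfig) -> tuple[pd.DataFrame, list]:
    if config.simulator is not None:
        records = generate_cohort(config.simulator)
        return cohort_frame(records), records
    raw = pd.read_csv(config.subject_table)
    if "subject_id" not in raw.columns:
        raw.insert(0, "subject_id", [f"S{i + 1:04d}" for i in range(len(raw))])
    return behavior.score_cohort(raw), []


def _build_adjacencies(config: RunConfig, cohort: pd.DataFrame, records) -> dict[str, np.ndarray]:
    adjs: dict[str, np.ndarray] = {}
    if config.simulator is not None:
        for rec in records:
            conn = generate_connectome(config.simulator, rec, mode=config.connectome_mode)
            adjs[rec.subject_id] = conn.values
        return adjs
    for sid in cohort["subject_id"]:
        if config.timeseries_dir is not None:
            ts = load_timeseries(Path(config.timeseries_dir) / f"{sid}.csv")
            conn = fisher_z_connectome(ts)
        else:
            conn = load_connectome(Path(config.connectome_dir) / f"{sid}.csv")
        adjs[sid] = proportional_threshold(conn, density=config.density).values
    return adjs


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full pipeline and write all stage outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("empanet").addHandler(handler)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ("sweep", "consensus", "screen", "plant"), ss.spawn(4)
        )
    }
    manifest["stage_seeds"] = stage_seeds

    with _stage("cohort", manifest):
        cohort, records = _load_cohort(config)
        cohort.to_csv(out / "subjects.csv", index=False)
        if config.simulator is not None:
            config.simulator.to_yaml(out / "simulator_config.yaml")
            manifest["subject_seeds"] = {r.subject_id: r.seed for r in records}

    with _stage("connectomes", manifest):
        adjacencies = _build_adjacencies(config, cohort, records)
        if config.save_connectomes:
            conn_dir = out / "connectomes"
            conn_dir.mkdir(exist_ok=True)
            for sid, adj in adjacencies.items():
                save_connectome(Connectome(adj, kind="binary"), conn_dir / f"{sid}.csv")

    with _stage("gamma_sweep", manifest):
        partitions: dict[float, dict[str, community.Partition]] = {g: {} for g in config.gammas}
        q_rows = []
        sweep_ss = np.random.SeedSequence(stage_seeds["sweep"])
        for (sid, adj), child in zip(adjacencies.items(), sweep_ss.spawn(len(adjacencies))):
            for part in community.gamma_sweep(
                adj, gammas=config.gammas, seed=int(child.generate_state(1)[0] % (2**31))
            ):
                partitions[part.gamma][sid] = part
                q_rows.append(
                    {"subject_id": sid, "gamma": part.gamma, "q": part.q,
                     "n_modules": part.n_modules}
                )
        q_table = pd.DataFrame(q_rows)
        q_table.to_csv(out / "modularity.csv", index=False)

    with _stage("consensus", manifest):
        consensus: dict[float, community.Partition] = {}
        module_keep: dict[float, pd.DataFrame] = {}
        part_dir = out / "partitions"
        part_dir.mkdir(exist_ok=True)
        cons_ss = np.random.SeedSequence(stage_seeds["consensus"])
        for g, child in zip(config.gammas, cons_ss.spawn(len(config.gammas))):
            subject_parts = list(partitions[g].values())
            agr = community.agreement(subject_parts)
            cons = community.consensus_partition(
                agr, reps=config.consensus_reps,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            cons = community.Partition(gamma=g, labels=cons.labels, q=cons.q)
            consensus[g] = cons
            keep = community.module_significance(
                cons, subject_parts, n_null=config.module_screen_nulls,
                seed=stage_seeds["screen"],
            )
            module_keep[g] = keep
            pd.DataFrame(
                {"node_id": np.arange(cons.n_nodes), "module_label": cons.labels}
            ).to_csv(part_dir / f"consensus_gamma_{g:g}.csv", index=False)
            keep.to_csv(part_dir / f"modules_gamma_{g:g}.csv", index=False)

    with _stage("metrics", manifest):
        rows = []
        for g in config.gammas:
            labels = consensus[g].labels
            for sid, adj in adjacencies.items():
                node_table = metrics.nodal_metrics(adj, labels)
                melted = node_table.melt(
                    id_vars="node_id", var_name="metric", value_name="value"
                )
                melted.insert(0, "subject_id", sid)
                melted.insert(2, "gamma", g)
                rows.append(melted)
        metric_table = pd.concat(rows, ignore_index=True)
        metric_table = metric_table[metric_table["metric"].isin(config.metric_names)]
        if config.simulator is not None:
            # superimpose the generative trait effect and noise structure on
            # the graph-derived baseline (the simulated study conditions)
            metric_table = plant_effect(
                metric_table, records, config.simulator,
                seed=stage_seeds["plant"],
            )
        metric_table.to_csv(out / "nodal_metrics.csv", index=False)

    with _stage("behavior", manifest):
        descriptives = behavior.behavioral_descriptives(cohort)
        mod_corr = {}
        for trait in config.traits:
            traits = cohort.set_index("subject_id")[f"{trait}_raw"].astype(float)
            per_gamma, mean_r, sd_r = community.modularity_trait_correlation(
                q_table, traits
            )
            mod_corr[trait] = {
                "per_gamma": per_gamma.to_dict(orient="records"),
                "mean_r": mean_r,
                "sd_r": sd_r,
            }
        with open(out / "behavior_descriptives.json", "w") as fh:
            json.dump(
                {"descriptives": descriptives.to_dict(),
                 "modularity_trait_correlation": mod_corr},
                fh, indent=2,
            )

    with _stage("association", manifest):
        results, blups, cross = _associate(
            config, cohort, metric_table, consensus, module_keep
        )
        results.to_csv(out / "associations.csv", index=False)
        blups.to_csv(out / "blups.csv", index=False)
        cross.to_csv(out / "associations_cross_gamma.csv", index=False)

    manifest["config"] = json.loads(json.dumps(asdict(config), default=str))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logging.getLogger("empanet").removeHandler(handler)
    handler.close()

    return RunResult(
        cohort=cohort,
        adjacencies=adjacencies,
        partitions=partitions,
        q_table=q_table,
        consensus=consensus,
        module_keep=module_keep,
        metric_table=metric_table,
        descriptives=descriptives,
        modularity_correlations=mod_corr,
        results=results,
        blups=blups,
        cross_gamma=cross,
        out_dir=out,
    )


def _associate(config, cohort, metric_table, consensus, module_keep):
    """Per-(gamma, trait) families of module x metric models, FDR, cross-gamma."""
    rows = []
    blup_rows = []
    fits = {}
    for g in config.gammas:
        keep = module_keep[g]
        kept_modules = [
            int(m) for m, k, size in zip(keep["module"], keep["keep"], keep["size"])
            if k and size >= 2
        ]
        for trait in config.traits:
            family = []
            for module in kept_modules:
                nodes = consensus[g].module_nodes(module)
                for metric_name in config.metric_names:
                    spec = assoc.ModelSpec(metric_name, trait, g, module)
                    table = assoc.build_long_table(
                        metric_table, cohort, g, nodes, metric_name, trait
                    )
                    try:
                        _, fit, _ = assoc.residual_screen(table, spec)
                    except ValueError as exc:
                        logger.warning(
                            "skipping gamma=%s module=%s metric=%s trait=%s: %s",
                            g, module, metric_name, trait, exc,
                        )
                        continue
                    fits[(g, trait, module, metric_name)] = (fit, table)
                    family.append((module, metric_name, fit))
            if not family:
                continue
            qvals = assoc.fdr_correct([f.beta_trait.p for _, _, f in family])
            for (module, metric_name, fit), qv in zip(family, qvals):
                fit.q = float(qv)
                rows.append(_result_row(fit))
                for node, b in fit.blups.items():
                    blup_rows.append(
                        {"gamma": g, "module": module, "metric": metric_name,
                         "trait": trait, "node_id": node, "blup": b}
                    )

    results = pd.DataFrame(rows)
    cross_rows = []
    if not results.empty:
        sig = results[results["q"] < config.fdr_q]
        for (trait, module, metric_name), sub in sig.groupby(["trait", "module", "metric"]):
            if len(sub) < 2:
                continue
            tables = [fits[(g, trait, module, metric_name)][1] for g in sub["gamma"]]
            spec = assoc.ModelSpec(metric_name, trait, None, int(module))
            fit = assoc.cross_gamma_model(tables, spec)
            row = _result_row(fit)
            row["gammas_pooled"] = ",".join(f"{g:g}" for g in sub["gamma"])
            cross_rows.append(row)
    blups = pd.DataFrame(blup_rows)
    return results, blups, pd.DataFrame(cross_rows)


def _result_row(fit: assoc.AssociationResult) -> dict:
    b, bi = fit.beta_trait, fit.beta_sex_interaction
    return {
        "gamma": fit.spec.gamma,
        "module": fit.spec.module,
        "metric": fit.spec.metric,
        "trait": fit.spec.trait,
        "beta": b.estimate, "se": b.se, "ci_low": b.ci_low, "ci_high": b.ci_high,
        "t": b.t, "p": b.p, "q": fit.q,
        "beta_sex_int": bi.estimate, "sex_int_se": bi.se, "sex_int_p": bi.p,
        "beta_female": fit.partial_beta_by_sex["female"],
        "beta_male": fit.partial_beta_by_sex["male"],
        "n_nodes_used": fit.n_nodes_used, "n_excluded": fit.n_excluded,
        "dropped_terms": ",".join(fit.dropped_terms),
    }
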