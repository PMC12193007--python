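"""End-to-end orchestration: simulate -> preprocess -> fit -> assign -> validate.

A single YAML/dict configuration drives every stage; one global seed is
expanded into independent per-stage child seeds so runs are bit
reproducible from (config, seed) alone. Every stage writes its
artifacts into the output directory and the run ends with a manifest
recording versions, seeds, per-stage runtimes and SHA-256 hashes of all
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assign import assign_subjects, assignments_to_frame
from .cohort import (HazardSpec, OutcomeSpec, SimulationConfig,
                     generate_cohort)
from .containers import BiomarkerMatrix, ConfigurationError
from .model import SubtypeStagingModel
from .preprocess import EventMixturePreprocessor
from .validate import cox_compare, logistic_association, nested_linear, subtype_contrasts

log = logging.getLogger("substage.pipeline")

STUDY_PRESET = dict(
    n_clusters=5,
    min_cluster_size=8,
    subtype_candidates=(2, 3, 4),
    mcmc_total=2_000_000,
    mcmc_burn_in=1_000_000,
    n_draw=1_000,
    significance_level=0.05,
)


@dataclass
class PipelineConfig:
    """Validated, normalized pipeline configuration."""

    output_dir: str = "substage_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    train_path: str | None = None
    validation_path: str | None = None
    survival_path: str | None = None
    outcome_paths: dict = field(default_factory=dict)
    binary_outcomes: tuple = ()
    n_clusters: int = STUDY_PRESET["n_clusters"]
    min_cluster_size: int = STUDY_PRESET["min_cluster_size"]
    subtype_candidates: tuple = STUDY_PRESET["subtype_candidates"]
    mcmc_total: int = STUDY_PRESET["mcmc_total"]
    mcmc_burn_in: int = STUDY_PRESET["mcmc_burn_in"]
    n_draw: int = STUDY_PRESET["n_draw"]
    n_restarts: int = 16
    significance_level: float = STUDY_PRESET["significance_level"]


def validate_config(raw: dict) -> PipelineConfig:
    """Normalize a raw config dict, filling documented defaults.

    All invariant violations are collected and raised together as one
    :class:`ConfigurationError`, not first-failure.
    """
    raw = dict(raw or {})
    errors = []
    sim = raw.pop("simulation", None)
    sim_cfg = None
    if sim is not None:
        if isinstance(sim, SimulationConfig):
            sim_cfg = sim
        else:
            sim = dict(sim)
            if "hazard" in sim and isinstance(sim["hazard"], dict):
                sim["hazard"] = HazardSpec(**sim["hazard"])
            if "outcomes" in sim:
                sim["outcomes"] = tuple(
                    o if isinstance(o, OutcomeSpec) else OutcomeSpec(**o)
                    for o in sim["outcomes"]
                )
            for key in ("orderings", "subtype_fractions", "apoe4_probs"):
                if key in sim:
                    sim[key] = tuple(
                        tuple(v) if isinstance(v, (list, tuple)) else v
                        for v in sim[key]
                    )
            try:
                sim_cfg = SimulationConfig(**sim)
                sim_cfg.validate()
            except ConfigurationError as err:
                errors.extend(err.errors)
            except TypeError as err:
                errors.append(str(err))
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known},
                         simulation=sim_cfg)
    cfg.subtype_candidates = tuple(int(c) for c in np.atleast_1d(cfg.subtype_candidates))
    cfg.outcome_paths = dict(cfg.outcome_paths)
    cfg.binary_outcomes = tuple(cfg.binary_outcomes)

    if cfg.mcmc_burn_in >= cfg.mcmc_total:
        errors.append(
            f"burn-in ({cfg.mcmc_burn_in}) must be below total MCMC samples "
            f"({cfg.mcmc_total})"
        )
    elif cfg.n_draw > cfg.mcmc_total - cfg.mcmc_burn_in:
        errors.append(
            f"n_draw ({cfg.n_draw}) exceeds retained samples "
            f"({cfg.mcmc_total - cfg.mcmc_burn_in})"
        )
    if not 0 < cfg.significance_level < 1:
        errors.append("significance_level must lie in (0, 1)")
    if cfg.n_clusters < 2:
        errors.append("n_clusters must be >= 2")
    if not cfg.subtype_candidates:
        errors.append("subtype_candidates must be non-empty")
    if errors:
        raise ConfigurationError(errors)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def run_pipeline(config: PipelineConfig | dict) -> dict:
    """Execute every pipeline stage and return the run manifest.

    A stage failure aborts the run with the stage name attached; partial
    artifacts written so far remain on disk.
    """
    if not isinstance(config, PipelineConfig):
        config = validate_config(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed, 5)
    manifest = {
        "package": "substage",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": dict(zip(["simulate", "preprocess", "fit", "assign", "validate"], seeds)),
        "stages": {},
    }

    def record(stage: str, t0: float, outputs: list[Path]):
        manifest["stages"][stage] = {
            "runtime_s": round(time.perf_counter() - t0, 3),
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
        }

    def run_stage(stage, fn):
        t0 = time.perf_counter()
        log.info("stage %s starting", stage)
        try:
            outputs = fn()
        except Exception as err:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
        record(stage, t0, outputs)
        log.info("stage %s done in %.2fs", stage,
                 manifest["stages"][stage]["runtime_s"])

    state: dict = {}

    # -- simulate / load -------------------------------------------------
    def simulate():
        if config.simulation is not None:
            sim = config.simulation.replace(seed=seeds[0])
            train, mci, survival, outcomes, truth = generate_cohort(sim)
            state.update(train=train, mci=mci, survival=survival,
                         outcomes=outcomes, truth=truth)
            paths = []
            for name, obj in (("train.csv", train), ("validation.csv", mci)):
                obj.to_csv(out / name)
                paths.append(out / name)
            survival.to_csv(out / "survival.csv")
            paths.append(out / "survival.csv")
            for name, tbl in outcomes.items():
                p = out / f"outcome_{name}.csv"
                tbl.to_csv(p)
                paths.append(p)
            truth.to_json(out / "ground_truth.json")
            paths.append(out / "ground_truth.json")
            (out / "simulation_config.json").write_text(
                json.dumps(sim.to_dict(), indent=1)
            )
            paths.append(out / "simulation_config.json")
            state["binary_outcomes"] = tuple(
                o.name for o in sim.outcomes if o.kind == "binary"
            )
            return paths
        missing = [
            k for k in ("train_path", "validation_path", "survival_path")
            if getattr(config, k) is None
        ]
        if missing:
            raise ConfigurationError(
                f"no simulation block and missing input paths: {missing}"
            )
        for k in ("train_path", "validation_path", "survival_path"):
            if not Path(getattr(config, k)).exists():
                raise ConfigurationError(f"input file not found: {getattr(config, k)}")
        state["train"] = BiomarkerMatrix.from_csv(config.train_path)
        state["mci"] = BiomarkerMatrix.from_csv(config.validation_path)
        state["survival"] = pd.read_csv(config.survival_path, index_col="subject_id")
        state["outcomes"] = {
            name: pd.read_csv(p, index_col="subject_id")
            for name, p in config.outcome_paths.items()
        }
        state["binary_outcomes"] = config.binary_outcomes
        return []

    run_stage("simulate", simulate)

    # -- preprocess ------------------------------------------------------
    def preprocess():
        pre = EventMixturePreprocessor().fit(state["train"])
        state["pre"] = pre
        state["epm_train"] = pre.transform(state["train"])
        state["epm_val"] = pre.transform(state["mci"])
        pre.save(out / "mixture_fits.json")
        pre.removal_log_.to_csv(out / "removal_log.tsv", sep="\t", index=False)
        return [out / "mixture_fits.json", out / "removal_log.tsv"]

    run_stage("preprocess", preprocess)

    # -- fit -------------------------------------------------------------
    def fit():
        est = SubtypeStagingModel(
            n_clusters=config.n_clusters,
            min_cluster_size=config.min_cluster_size,
            n_subtypes=config.subtype_candidates,
            n_mcmc=config.mcmc_total,
            n_burn_in=config.mcmc_burn_in,
            n_draw=config.n_draw,
            n_restarts=config.n_restarts,
            random_state=seeds[2],
        ).fit(state["epm_train"])
        state["est"] = est
        est.model_.to_json(out / "subtype_model.json")
        est.clustering_.to_series().to_csv(out / "event_clusters.csv")
        summary = {
            "selected_subtypes": est.n_subtypes_,
            "candidate_log_likelihoods": {
                str(k): v for k, v in est.candidate_log_likelihoods_.items()
            },
            "mcmc_acceptance_rate": est.posterior_.acceptance_rate,
        }
        (out / "fit_summary.json").write_text(json.dumps(summary, indent=1))
        return [out / "subtype_model.json", out / "event_clusters.csv",
                out / "fit_summary.json"]

    run_stage("fit", fit)

    # -- assign ----------------------------------------------------------
    def assign():
        est = state["est"]
        assignments = assign_subjects(
            state["epm_val"], est.clustering_, est.posterior_,
            n_draw=config.n_draw, seed=seeds[3],
        )
        frame = assignments_to_frame(assignments)
        state["assignments"] = frame
        frame.to_csv(out / "assignments.csv")
        return [out / "assignments.csv"]

    run_stage("assign", assign)

    # -- validate --------------------------------------------------------
    def validate():
        frame = state["assignments"]
        surv = state["survival"].copy()
        inferred = frame[["subtype", "stage"]].reindex(surv.index)
        surv["stage"] = inferred["stage"]
        surv["subtype"] = inferred["subtype"]
        comparison = cox_compare(surv)
        report = {
            "significance_level": config.significance_level,
            "cox": {
                "base": {"c_index": comparison.base.concordance_index,
                         "aic": comparison.base.aic},
                "full": {"c_index": comparison.full.concordance_index,
                         "aic": comparison.full.aic},
                "logrank_stage_p": comparison.logrank_stage_p,
            },
            "associations": {},
        }
        comparison.forest_table().to_csv(out / "cox_forest.tsv", sep="\t", index=False)
        cov = surv[["age", "gender", "education", "apoe4"]]
        for name, tbl in state["outcomes"].items():
            y = tbl["value"].reindex(surv.index)
            if name in state.get("binary_outcomes", ()):
                rep = logistic_association(
                    y.rename(name), cov, surv["stage"], surv["subtype"])
            else:
                rep = nested_linear(y.rename(name), cov, surv["stage"], surv["subtype"])
                rep.contrasts = subtype_contrasts(
                    y.rename(name), surv["subtype"], cov, surv["stage"])
            report["associations"][name] = rep.to_dict()
        (out / "validation_report.json").write_text(json.dumps(report, indent=1))
        return [out / "validation_report.json", out / "cox_forest.tsv"]

    run_stage("validate", validate)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
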