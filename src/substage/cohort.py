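"""Synthetic cohort generation with planted subtype/stage ground truth.

The generator emulates the structure of an ADNI-style cross-sectional
study: a training arm of cognitively normal controls (CN, all at stage 0)
and dementia patients (AD, concentrated on the last two stages), plus an
MCI validation arm spanning all stages, with latent progression subtypes
defined by distinct orderings of K event clusters. Downstream tables —
time-to-conversion with administrative censoring under a proportional
hazards model, and continuous/binary outcome scores linear (or logistic)
in stage after covariate effects — are drawn from the same latent state,
so parameter recovery can be checked at every pipeline stage.

Biomarker values are two-component Gaussian: a feature in cluster k of a
subject with ordering sigma and stage s is drawn from the abnormal
component iff k occurs among the first s entries of sigma. A random
subset of features has its sign flipped (ventricle-like markers that
*increase* with disease) to exercise orientation; a configurable number
of columns are exactly constant, and one is standard Cauchy so that the
mixture-fittability filter has something to catch.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import BiomarkerMatrix, ConfigurationError

# Four well-separated orderings of five event clusters (0-based internal
# representation), loosely emulating subcortical-first / cortical-first /
# disconnection / frontal progression archetypes. They are chosen so that
# the *set* of transitioned clusters differs between every pair of
# subtypes at every intermediate stage 1..K-1: a subject's subtype is
# then identifiable from a single visit whenever progression is partial
# (at stages 0 and K all orderings explain the data identically, a
# structural property of any event-ordering model).
DEFAULT_ORDERINGS_K5 = (
    (0, 1, 2, 3, 4),
    (4, 3, 2, 1, 0),
    (2, 0, 4, 1, 3),
    (3, 1, 4, 0, 2),
)


@dataclass(frozen=True)
class OutcomeSpec:
    """One downstream outcome drawn from the latent disease state."""

    name: str
    kind: str                      # "continuous" | "binary"
    intercept: float
    stage_coef: float
    covariate_coefs: dict = field(default_factory=dict)
    noise_sd: float = 1.0          # ignored for binary outcomes

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ConfigurationError(f"unknown outcome kind {self.kind!r}")


@dataclass(frozen=True)
class HazardSpec:
    """Proportional-hazards conversion model for the MCI arm.

    ``baseline_rate`` is the per-month hazard of a stage-0 subject of the
    reference subtype with covariates at zero effect; stage and subtype
    act multiplicatively through their log hazard ratios.
    """

    baseline_rate: float = 0.0004
    stage_log_hr: float = math.log(1.77)
    subtype_log_hr: tuple = (0.0, math.log(2.50), math.log(2.03), math.log(2.24))
    age_log_hr: float = 0.03
    gender_log_hr: float = 0.10
    education_log_hr: float = -0.03
    apoe4_log_hr: float = 0.45


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic cohort.

    Defaults reproduce the study conditions the package is tested
    against: 123 raw features (4 zero-variance, 1 heavy-tailed, 118
    informative), 5 event clusters (six stages 0..5), 4 subtypes with
    distinct orderings, CN/AD training arms of 504/346 and an MCI
    validation arm of 808, and a per-stage conversion hazard ratio
    of 1.77.
    """

    n_features: int = 123
    n_zero_variance: int = 4
    n_heavy_tailed: int = 1
    n_clusters: int = 5
    min_features_per_cluster: int = 8
    n_subtypes: int = 4
    orderings: tuple = DEFAULT_ORDERINGS_K5
    subtype_fractions: tuple = (0.40, 0.25, 0.20, 0.15)
    effect_size: float = 2.0
    flip_fraction: float = 0.3     # fraction of features measured on an inverted scale
    n_cn: int = 504
    n_ad: int = 346
    n_mci: int = 808
    age_mean: float = 73.0
    age_sd: float = 7.0
    prob_male: float = 0.55
    education_mean: float = 16.0
    education_sd: float = 2.7
    apoe4_probs: tuple = (0.55, 0.35, 0.10)
    hazard: HazardSpec = HazardSpec()
    censoring_horizon: float = 96.0   # months
    outcomes: tuple = (
        OutcomeSpec(
            "delayed_recall", "continuous", 12.0, -0.8,
            {"age": -0.05, "education": 0.2, "apoe4": -0.3}, 2.5,
        ),
        OutcomeSpec(
            "fdg_pet", "continuous", 1.35, -0.035,
            {"age": -0.002, "apoe4": -0.01}, 0.12,
        ),
        OutcomeSpec(
            "pentagon_correct", "binary", 2.5, -0.33,
            {"education": 0.05, "age": -0.02},
        ),
    )
    seed: int = 0

    # ------------------------------------------------------------------
    @property
    def n_informative(self) -> int:
        return self.n_features - self.n_zero_variance - self.n_heavy_tailed

    @property
    def n_stages(self) -> int:
        return self.n_clusters + 1

    def validate(self) -> None:
        errors = []
        K, C = self.n_clusters, self.n_subtypes
        if abs(sum(self.subtype_fractions) - 1.0) > 1e-12:
            errors.append(
                f"subtype_fractions sum to {sum(self.subtype_fractions)!r}, expected 1"
            )
        if len(self.subtype_fractions) != C:
            errors.append("len(subtype_fractions) != n_subtypes")
        if len(self.orderings) != C:
            errors.append("len(orderings) != n_subtypes")
        for c, sigma in enumerate(self.orderings):
            if sorted(sigma) != list(range(K)):
                errors.append(
                    f"ordering {c + 1} is not a permutation of 0..{K - 1}: {sigma}"
                )
        needed = K * self.min_features_per_cluster + self.n_zero_variance + self.n_heavy_tailed
        if self.n_features < needed:
            errors.append(
                "infeasible feature allocation: n_features "
                f"({self.n_features}) < n_clusters * min_features_per_cluster "
                f"+ n_zero_variance + n_heavy_tailed ({needed})"
            )
        if not 0 <= self.flip_fraction <= 1:
            errors.append("flip_fraction must lie in [0, 1]")
        if abs(sum(self.apoe4_probs) - 1.0) > 1e-12:
            errors.append("apoe4_probs must sum to 1")
        if self.effect_size < 0:
            errors.append("effect_size must be nonnegative")
        if errors:
            raise ConfigurationError(errors)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            return obj

        out = {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}
        return out


def default_study_config() -> SimulationConfig:
    """Study-scale default configuration (123 raw features, 5 clusters,
    6 stages, 4 subtypes, per-stage hazard ratio 1.77)."""
    cfg = SimulationConfig()
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    """Latent state planted by :func:`generate_cohort`."""

    subtype: pd.Series            # 1-based subtype per subject (all arms)
    stage: pd.Series              # 0..K per subject
    feature_clusters: dict        # informative feature name -> cluster id (1-based)
    orderings: np.ndarray         # (C, K), 0-based cluster indices
    orientation_signs: dict       # feature name -> +1 / -1
    subtype_fractions: np.ndarray

    def to_json(self, path: str | Path) -> None:
        doc = {
            "subtype": {str(k): int(v) for k, v in self.subtype.items()},
            "stage": {str(k): int(v) for k, v in self.stage.items()},
            "feature_clusters": {k: int(v) for k, v in self.feature_clusters.items()},
            "orderings": self.orderings.tolist(),
            "orientation_signs": {k: int(v) for k, v in self.orientation_signs.items()},
            "subtype_fractions": list(map(float, self.subtype_fractions)),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            subtype=pd.Series(doc["subtype"]),
            stage=pd.Series(doc["stage"]),
            feature_clusters=doc["feature_clusters"],
            orderings=np.asarray(doc["orderings"], dtype=int),
            orientation_signs=doc["orientation_signs"],
            subtype_fractions=np.asarray(doc["subtype_fractions"], dtype=float),
        )


# ---------------------------------------------------------------------------


def _draw_covariates(rng: np.random.Generator, n: int, cfg: SimulationConfig):
    return pd.DataFrame(
        {
            "age": rng.normal(cfg.age_mean, cfg.age_sd, n).round(1),
            "gender": rng.binomial(1, cfg.prob_male, n),
            "education": np.clip(
                rng.normal(cfg.education_mean, cfg.education_sd, n).round(0), 6, 20
            ),
            "apoe4": rng.choice(3, size=n, p=cfg.apoe4_probs),
        }
    )


def _allocate_clusters(cfg: SimulationConfig) -> np.ndarray:
    """Round-robin assignment of informative features to clusters."""
    return np.arange(cfg.n_informative) % cfg.n_clusters


def _feature_values(
    rng: np.random.Generator,
    stages: np.ndarray,
    subtypes0: np.ndarray,
    cluster_of: np.ndarray,
    orderings: np.ndarray,
    effect_size: float,
) -> np.ndarray:
    """Draw informative feature values given latent state.

    ``position[c, k]`` is the rank of cluster k in subtype c's ordering;
    cluster k is abnormal for a subject iff position < stage.
    """
    C, K = orderings.shape
    position = np.empty((C, K), dtype=int)
    for c in range(C):
        position[c, orderings[c]] = np.arange(K)
    # (n_subjects, K) boolean: which clusters have transitioned
    abnormal_cluster = position[subtypes0] < stages[:, None]
    abnormal = abnormal_cluster[:, cluster_of]          # (n, n_informative)
    n = len(stages)
    return abnormal * effect_size + rng.normal(size=(n, len(cluster_of)))


def _assemble_matrix(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    informative: np.ndarray,
    ids: list,
    covariates: pd.DataFrame,
    diagnosis: np.ndarray,
    signs: np.ndarray,
    column_order: np.ndarray,
    names: list,
) -> BiomarkerMatrix:
    n = len(ids)
    zero_block = np.ones((n, cfg.n_zero_variance)) * np.arange(1, cfg.n_zero_variance + 1)
    heavy_block = rng.standard_cauchy((n, cfg.n_heavy_tailed))
    raw = np.hstack([informative * signs, zero_block, heavy_block])
    values = pd.DataFrame(raw[:, column_order], index=ids, columns=names)
    subjects = covariates.copy()
    subjects.insert(0, "diagnosis", diagnosis)
    subjects.index = ids
    return BiomarkerMatrix(subjects, values)


def generate_cohort(config: SimulationConfig):
    """Generate training/validation biomarker tables plus survival,
    outcome and ground-truth records.

    Returns
    -------
    (train, mci, survival, outcomes, truth) where ``train`` pools the CN
    and AD arms, ``survival`` is a per-MCI-subject table with columns
    ``time`` (months), ``event``, covariates, true ``stage``/``subtype``,
    ``outcomes`` maps outcome name -> DataFrame, and ``truth`` is the
    planted :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    K, C = config.n_clusters, config.n_subtypes
    orderings = np.asarray(config.orderings, dtype=int)
    fractions = np.asarray(config.subtype_fractions, dtype=float)

    # feature bookkeeping ------------------------------------------------
    cluster_of = _allocate_clusters(config)
    info_names = [f"marker_{i:03d}" for i in range(config.n_informative)]
    zero_names = [f"zerovar_{j + 1}" for j in range(config.n_zero_variance)]
    heavy_names = [f"heavytail_{j + 1}" for j in range(config.n_heavy_tailed)]
    all_names = info_names + zero_names + heavy_names
    column_order = rng.permutation(len(all_names))
    names = [all_names[i] for i in column_order]
    signs = np.where(
        rng.random(config.n_informative) < config.flip_fraction, -1.0, 1.0
    )

    # latent state -------------------------------------------------------
    n_total = config.n_cn + config.n_ad + config.n_mci
    diagnosis = np.array(
        ["CN"] * config.n_cn + ["AD"] * config.n_ad + ["MCI"] * config.n_mci
    )
    subtypes0 = rng.choice(C, size=n_total, p=fractions)       # 0-based
    stages = np.empty(n_total, dtype=int)
    stages[: config.n_cn] = 0
    stages[config.n_cn : config.n_cn + config.n_ad] = rng.integers(
        K - 1, K + 1, size=config.n_ad
    )
    stages[config.n_cn + config.n_ad :] = rng.integers(
        0, K + 1, size=config.n_mci
    )
    ids = [f"S{i:05d}" for i in range(n_total)]
    covariates = _draw_covariates(rng, n_total, config)

    informative = _feature_values(
        rng, stages, subtypes0, cluster_of, orderings, config.effect_size
    )
    matrix = _assemble_matrix(
        rng, config, informative, ids, covariates, diagnosis, signs,
        column_order, names,
    )
    train = matrix.arm("CN")
    train = BiomarkerMatrix(
        pd.concat([train.subjects, matrix.arm("AD").subjects]),
        pd.concat([train.values, matrix.arm("AD").values]),
    )
    mci = matrix.arm("MCI")

    # survival table (MCI arm) ------------------------------------------
    mci_mask = diagnosis == "MCI"
    hz = config.hazard
    cov = covariates[mci_mask].reset_index(drop=True)
    lin = (
        hz.stage_log_hr * stages[mci_mask]
        + np.asarray(hz.subtype_log_hr)[subtypes0[mci_mask]]
        + hz.age_log_hr * (cov["age"] - config.age_mean)
        + hz.gender_log_hr * cov["gender"]
        + hz.education_log_hr * (cov["education"] - config.education_mean)
        + hz.apoe4_log_hr * cov["apoe4"]
    )
    rate = hz.baseline_rate * np.exp(lin.to_numpy())
    latent_time = rng.exponential(1.0 / rate)
    event = (latent_time <= config.censoring_horizon).astype(int)
    time = np.minimum(latent_time, config.censoring_horizon)
    mci_ids = [i for i, m in zip(ids, mci_mask) if m]
    survival = pd.DataFrame(
        {
            "time": np.maximum(time, 1e-6),
            "event": event,
            **{c: cov[c].to_numpy() for c in cov.columns},
            "stage": stages[mci_mask],
            "subtype": subtypes0[mci_mask] + 1,
        },
        index=pd.Index(mci_ids, name="subject_id"),
    )

    # outcome tables (MCI arm) ------------------------------------------
    outcomes = {}
    for spec in config.outcomes:
        eta = spec.intercept + spec.stage_coef * stages[mci_mask]
        for cname, coef in spec.covariate_coefs.items():
            center = {"age": config.age_mean, "education": config.education_mean}.get(
                cname, 0.0
            )
            eta = eta + coef * (cov[cname].to_numpy() - center)
        if spec.kind == "continuous":
            y = eta + rng.normal(0.0, spec.noise_sd, mci_mask.sum())
        else:
            y = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
        outcomes[spec.name] = pd.DataFrame(
            {"value": y}, index=pd.Index(mci_ids, name="subject_id")
        )

    truth = GroundTruth(
        subtype=pd.Series(subtypes0 + 1, index=ids, name="subtype"),
        stage=pd.Series(stages, index=ids, name="stage"),
        feature_clusters={
            name: int(cluster_of[i]) + 1 for i, name in enumerate(info_names)
        },
        orderings=orderings,
        orientation_signs={
            name: int(signs[i]) for i, name in enumerate(info_names)
        },
        subtype_fractions=fractions,
    )
    return train, mci, survival, outcomes, truth
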