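"""Core data containers shared across the package.

``BiomarkerMatrix`` is the tabular interchange object for cross-sectional
cohorts: one row per subject carrying a diagnosis label, the standard
demographic/genetic covariates and a block of biomarker feature columns.
``EventProbabilityMatrix`` holds, per subject and feature, the two
component densities of the fitted normal/abnormal mixture and the
posterior probability that the feature has undergone its event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

COVARIATES = ("age", "gender", "education", "apoe4")
DIAGNOSES = ("CN", "AD", "MCI")


class ConfigurationError(ValueError):
    """Invalid configuration; ``errors`` lists every violation found."""

    def __init__(self, errors: Sequence[str] | str):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class FitError(RuntimeError):
    """A model fit failed in a way that cannot be represented as a flag."""


class BiomarkerMatrix:
    """Subjects x biomarkers with diagnosis labels and covariates.

    Parameters
    ----------
    subjects : DataFrame indexed by unique subject id with columns
        ``diagnosis`` (one of CN/AD/MCI), ``age``, ``gender`` (0 = female,
        1 = male), ``education``, ``apoe4`` (allele count 0/1/2).
    values : DataFrame of biomarker values aligned on the same index;
        missing entries are allowed and propagate as NaN.
    """

    def __init__(self, subjects: pd.DataFrame, values: pd.DataFrame):
        subjects = subjects.copy()
        values = values.copy()
        if not subjects.index.is_unique:
            raise ConfigurationError("subject ids must be unique")
        if not subjects.index.equals(values.index):
            raise ConfigurationError("subject and value tables must share an index")
        missing = [c for c in ("diagnosis", *COVARIATES) if c not in subjects.columns]
        if missing:
            raise ConfigurationError(f"subject table lacks columns: {missing}")
        bad_dx = set(subjects["diagnosis"]) - set(DIAGNOSES)
        if bad_dx:
            raise ConfigurationError(f"unknown diagnosis labels: {sorted(bad_dx)}")
        bad_apoe = set(pd.unique(subjects["apoe4"].dropna())) - {0, 1, 2}
        if bad_apoe:
            raise ConfigurationError(f"apoe4 must be in {{0,1,2}}, got {sorted(bad_apoe)}")
        self.subjects = subjects
        self.values = values

    # -- basic accessors -------------------------------------------------
    @property
    def subject_ids(self) -> pd.Index:
        return self.subjects.index

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def diagnosis(self) -> pd.Series:
        return self.subjects["diagnosis"]

    def arm(self, diagnosis: str) -> "BiomarkerMatrix":
        mask = self.subjects["diagnosis"] == diagnosis
        return BiomarkerMatrix(self.subjects[mask], self.values[mask])

    def select_features(self, names: Iterable[str]) -> "BiomarkerMatrix":
        return BiomarkerMatrix(self.subjects, self.values[list(names)])

    def copy(self) -> "BiomarkerMatrix":
        return BiomarkerMatrix(self.subjects, self.values)

    # -- IO --------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.subjects, self.values], axis=1)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="subject_id")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BiomarkerMatrix":
        meta_cols = ["diagnosis", *COVARIATES]
        feats = [c for c in frame.columns if c not in meta_cols]
        return cls(frame[meta_cols], frame[feats])

    @classmethod
    def from_csv(cls, path: str | Path) -> "BiomarkerMatrix":
        return cls.from_frame(pd.read_csv(path, index_col="subject_id"))

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"BiomarkerMatrix({self.n_subjects} subjects, "
            f"{len(self.feature_names)} features)"
        )


@dataclass
class EventProbabilityMatrix:
    """Per-observation mixture densities and event posteriors.

    ``log_f_ab`` / ``log_f_no`` are the log densities of the abnormal and
    normal mixture components evaluated at each observation; missing
    observations carry log density 0 for both components (density 1, i.e.
    uninformative) and posterior 0.5.
    """

    subject_ids: pd.Index
    feature_names: list[str]
    p_event: np.ndarray          # (n_subjects, n_features) in [0, 1]
    log_f_ab: np.ndarray         # (n_subjects, n_features)
    log_f_no: np.ndarray         # (n_subjects, n_features)
    missing: np.ndarray = field(default=None)  # boolean mask, optional

    def __post_init__(self):
        self.p_event = np.asarray(self.p_event, dtype=float)
        self.log_f_ab = np.asarray(self.log_f_ab, dtype=float)
        self.log_f_no = np.asarray(self.log_f_no, dtype=float)
        n, d = self.p_event.shape
        if len(self.subject_ids) != n or len(self.feature_names) != d:
            raise ValueError("shape mismatch between labels and matrices")
        if self.missing is None:
            self.missing = np.zeros((n, d), dtype=bool)
        if np.any(self.p_event < 0) or np.any(self.p_event > 1):
            raise ValueError("event probabilities must lie in [0, 1]")

    @property
    def n_subjects(self) -> int:
        return self.p_event.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.p_event, index=self.subject_ids, columns=self.feature_names
        )

    def subset(self, rows: np.ndarray) -> "EventProbabilityMatrix":
        return EventProbabilityMatrix(
            self.subject_ids[rows],
            self.feature_names,
            self.p_event[rows],
            self.log_f_ab[rows],
            self.log_f_no[rows],
            self.missing[rows],
        )
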