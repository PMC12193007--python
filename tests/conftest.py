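import numpy as np
import pandas as pd
import pytest

import substage
from substage import (BiomarkerMatrix, EventProbabilityMatrix,
                      EventMixturePreprocessor, default_study_config,
                      generate_cohort)


@pytest.fixture(scope="session")
def paper_cohort():
    """Study-scale synthetic cohort (123 raw features, CN/AD/MCI arms)."""
    cfg = default_study_config().replace(seed=1)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def paper_preprocessor(paper_cohort):
    train = paper_cohort[0]
    return EventMixturePreprocessor().fit(train)


@pytest.fixture(scope="session")
def paper_epm_train(paper_cohort, paper_preprocessor):
    return paper_preprocessor.transform(paper_cohort[0])


def make_matrix(values: np.ndarray, diagnosis, feature_names=None, seed=0):
    """Wrap a raw value array into a BiomarkerMatrix with stock covariates."""
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    feature_names = feature_names or [f"f{j}" for j in range(values.shape[1])]
    ids = pd.Index([f"S{i:04d}" for i in range(n)], name="subject_id")
    subjects = pd.DataFrame(
        {
            "diagnosis": diagnosis,
            "age": rng.normal(73, 7, n).round(1),
            "gender": rng.integers(0, 2, n),
            "education": rng.integers(12, 20, n),
            "apoe4": rng.integers(0, 3, n),
        },
        index=ids,
    )
    values = pd.DataFrame(values, index=ids, columns=feature_names)
    return BiomarkerMatrix(subjects, values)


def make_epm(log_ab: np.ndarray, log_no: np.ndarray) -> EventProbabilityMatrix:
    """EPM directly from component log densities (p_event from the
    density ratio at weight 0.5)."""
    log_ab = np.asarray(log_ab, dtype=float)
    log_no = np.asarray(log_no, dtype=float)
    p = 1.0 / (1.0 + np.exp(log_no - log_ab))
    ids = pd.Index([f"S{i:04d}" for i in range(log_ab.shape[0])])
    names = [f"f{j}" for j in range(log_ab.shape[1])]
    return EventProbabilityMatrix(ids, names, p, log_ab, log_no)


@pytest.fixture
def matrix_factory():
    return make_matrix


@pytest.fixture
def epm_factory():
    return make_epm
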