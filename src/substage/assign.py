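"""Out-of-sample subtyping and staging of held-out subjects.

Held-out subjects (typically the MCI validation arm) are assigned by
averaging their joint (subtype, stage) posterior over a random draw of
stored MCMC samples, using the training-cohort mixture fits and event
clustering unchanged. For sample m with orderings sigma^(m) and
fractions f^(m), the joint weight of subject i is

    w_m(c, s)  propto  f_c^(m) pi(s) P(x_i | sigma_c^(m), s)

normalised over all (c, s); the reported posterior is the mean of w_m
over the drawn samples. Point labels are marginal argmaxes (ties go to
the smaller index); a per-sample majority-vote variant is available via
``method="vote"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .containers import ConfigurationError, EventProbabilityMatrix
from .model import ClusterDensities, EventClustering, PosteriorSamples


@dataclass
class SubjectAssignment:
    """Per-subject joint posterior over (subtype, stage) and point labels."""

    subject_id: object
    posterior: np.ndarray        # (C, K+1), entries >= 0, sums to 1
    subtype: int                 # 1-based point label
    stage: int
    expected_stage: float
    max_posterior: float
    n_samples_used: int

    def __post_init__(self):
        if abs(self.posterior.sum() - 1.0) > 1e-9 or (self.posterior < 0).any():
            raise ValueError("posterior must be a distribution over (subtype, stage)")


def assign_subjects(epm: EventProbabilityMatrix, clustering: EventClustering,
                    posterior: PosteriorSamples, n_draw: int,
                    seed: int | None = None,
                    method: str = "average") -> list[SubjectAssignment]:
    """Stage and subtype every subject of ``epm``.

    ``n_draw`` MCMC samples are drawn without replacement from the
    stored post-burn-in samples. Subjects whose likelihood underflows to
    zero at every (subtype, stage) receive a uniform posterior and a
    warning. ``method="vote"`` replaces posterior averaging with a
    per-sample argmax majority vote for the point labels (the averaged
    posterior is still reported).
    """
    if seed is None:
        raise ConfigurationError("assignment is stochastic: a seed is required")
    if n_draw > posterior.n_samples:
        raise ConfigurationError(
            f"n_draw ({n_draw}) exceeds stored samples ({posterior.n_samples})"
        )
    if method not in ("average", "vote"):
        raise ConfigurationError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(posterior.n_samples, size=n_draw, replace=False)
    dens = ClusterDensities(epm, clustering)
    n, K = dens.n_subjects, dens.n_clusters
    C = posterior.orderings.shape[1]
    log_prior = -np.log(K + 1)

    # cache stage log-likelihood matrices per distinct ordering
    cache: dict[bytes, np.ndarray] = {}

    def stage_ll(sigma: np.ndarray) -> np.ndarray:
        key = sigma.tobytes()
        if key not in cache:
            cache[key] = dens.stage_log_likelihoods(sigma.astype(int))
        return cache[key]

    mean_post = np.zeros((n, C, K + 1))
    votes = np.zeros((n, C, K + 1), dtype=int)
    degenerate = np.zeros(n, dtype=bool)
    for m in idx:
        o = posterior.orderings[m]
        f = posterior.fractions[m]
        logj = np.empty((n, C, K + 1))
        for c in range(C):
            with np.errstate(divide="ignore"):
                logj[:, c, :] = stage_ll(o[c]) + np.log(f[c]) + log_prior
        flat = logj.reshape(n, -1)
        norm = logsumexp(flat, axis=1)
        bad = ~np.isfinite(norm)
        degenerate |= bad
        w = np.exp(flat - np.where(bad, 0.0, norm)[:, None])
        w[bad] = 1.0 / (C * (K + 1))
        w = w.reshape(n, C, K + 1)
        mean_post += w
        if method == "vote":
            top = flat.argmax(axis=1)
            votes.reshape(n, -1)[np.arange(n), top] += 1
    mean_post /= n_draw
    if degenerate.any():
        ids = list(np.asarray(epm.subject_ids)[degenerate])
        warnings.warn(
            f"uniform posterior assigned to {degenerate.sum()} subject(s) with "
            f"vanishing likelihood: {ids[:5]}"
        )

    out = []
    for i, sid in enumerate(epm.subject_ids):
        post = mean_post[i]
        basis = votes[i] if method == "vote" else post
        subtype_marg = basis.sum(axis=1)
        stage_marg = basis.sum(axis=0)
        subtype = int(subtype_marg.argmax()) + 1     # argmax takes smallest on ties
        stage = int(stage_marg.argmax())
        expected = float(np.arange(K + 1) @ post.sum(axis=0))
        out.append(SubjectAssignment(
            sid, post, subtype, stage, expected, float(post.max()), n_draw,
        ))
    return out


def assignments_to_frame(assignments: list[SubjectAssignment]) -> pd.DataFrame:
    """Flatten assignments to the CSV layout: point labels, expected
    stage, max posterior probability and one column per (c, s) cell."""
    rows = []
    for a in assignments:
        C, S = a.posterior.shape
        row = {
            "subject_id": a.subject_id,
            "subtype": a.subtype,
            "stage": a.stage,
            "expected_stage": a.expected_stage,
            "max_posterior": a.max_posterior,
        }
        for c in range(C):
            for s in range(S):
                row[f"p_subtype{c + 1}_stage{s}"] = a.posterior[c, s]
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")
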