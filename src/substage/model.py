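"""Clustered event-based progression model with subtypes.

The model groups biomarkers into K event clusters that transition from
normal to abnormal together, so a disease trajectory is a permutation
(ordering) of the K clusters and a subject's stage s in {0..K} counts how
many clusters have transitioned. A population is a mixture of C
subtypes, each with its own ordering sigma_c and mixing fraction f_c.
With per-observation component densities f_no / f_ab from the biomarker
mixtures, the data likelihood of subject i is

    P(x_i) = sum_c f_c sum_{s=0}^{K} pi(s)
             prod_{r <= s} prod_{j in cluster sigma_c(r)} f_ab(x_ij)
             prod_{r >  s} prod_{j in cluster sigma_c(r)} f_no(x_ij)

with a uniform stage prior pi(s) = 1/(K+1). Orderings are fitted by
greedy pairwise-swap ascent inside a hierarchical split scheme (fit one
subtype, then repeatedly split the worst-explained subtype and
re-optimise), and posterior uncertainty is characterised with
Metropolis-Hastings sampling over orderings and fractions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .containers import ConfigurationError, EventProbabilityMatrix, FitError

_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Event clustering
# ---------------------------------------------------------------------------


@dataclass
class EventClustering:
    """Partition of retained features into K compound events."""

    feature_names: list[str]
    labels: np.ndarray           # 0-based cluster id per feature
    n_clusters: int
    min_cluster_size: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        sizes = np.bincount(self.labels, minlength=self.n_clusters)
        if len(self.labels) != len(self.feature_names):
            raise ValueError("labels/feature_names length mismatch")
        if set(self.labels) != set(range(self.n_clusters)):
            raise ValueError("labels must cover clusters 0..K-1 exactly")
        if (sizes < self.min_cluster_size).any():
            raise ValueError(
                f"cluster sizes {sizes.tolist()} below minimum {self.min_cluster_size}"
            )

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    def to_series(self) -> pd.Series:
        """1-based cluster id per feature (external convention)."""
        return pd.Series(self.labels + 1, index=self.feature_names, name="cluster")

    def members(self, k: int) -> list[str]:
        return [f for f, l in zip(self.feature_names, self.labels) if l == k]


def cluster_events(epm: EventProbabilityMatrix, n_clusters: int,
                   min_cluster_size: int = 1) -> EventClustering:
    """Agglomerative (average linkage) clustering of features on
    correlation distance between their event-probability vectors.

    The dendrogram is first cut at K clusters; if any cluster falls below
    the minimum size, undersized clusters are merged into their nearest
    neighbour (average correlation distance between members) and the cut
    is deepened until exactly K clusters of admissible size remain.
    """
    d = len(epm.feature_names)
    if n_clusters < 2:
        raise ConfigurationError("n_clusters must be >= 2")
    if d < n_clusters * min_cluster_size:
        raise ConfigurationError(
            f"{d} features cannot form {n_clusters} clusters of size "
            f">= {min_cluster_size}"
        )
    P = epm.p_event
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(P.T)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = linkage(squareform(dist, checks=False), method="average")

    def _merge_undersized(labels: np.ndarray) -> np.ndarray:
        labels = labels.copy()
        while True:
            ids, sizes = np.unique(labels, return_counts=True)
            if len(ids) <= 1:
                break
            small = ids[sizes < min_cluster_size]
            if len(small) == 0:
                break
            k = small[np.argmin(sizes[np.isin(ids, small)])]
            mask_k = labels == k
            best, best_d = None, np.inf
            for other in ids:
                if other == k:
                    continue
                dd = dist[np.ix_(mask_k, labels == other)].mean()
                if dd < best_d:
                    best, best_d = other, dd
            labels[mask_k] = best
        return labels

    for cut in range(n_clusters, d + 1):
        labels = fcluster(Z, t=cut, criterion="maxclust") - 1
        labels = _merge_undersized(labels)
        ids = np.unique(labels)
        if len(ids) == n_clusters:
            remap = {old: new for new, old in enumerate(ids)}
            labels = np.array([remap[l] for l in labels])
            return EventClustering(
                list(epm.feature_names), labels, n_clusters, min_cluster_size
            )
    raise ConfigurationError(
        f"could not form {n_clusters} clusters of size >= {min_cluster_size}"
    )


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


class ClusterDensities:
    """Per-subject, per-cluster summed log component densities.

    ``a[i, k]`` / ``b[i, k]`` are the log products of abnormal / normal
    component densities over all features of cluster k for subject i;
    stage log-likelihoods along any ordering are cumulative sums of
    ``a - b`` plus the all-normal baseline.
    """

    def __init__(self, epm: EventProbabilityMatrix, clustering: EventClustering):
        order = [epm.feature_names.index(f) for f in clustering.feature_names]
        log_ab = epm.log_f_ab[:, order]
        log_no = epm.log_f_no[:, order]
        K = clustering.n_clusters
        n = epm.n_subjects
        self.n_subjects, self.n_clusters = n, K
        self.subject_ids = epm.subject_ids
        self.a = np.zeros((n, K))
        self.b = np.zeros((n, K))
        for k in range(K):
            cols = clustering.labels == k
            self.a[:, k] = log_ab[:, cols].sum(axis=1)
            self.b[:, k] = log_no[:, cols].sum(axis=1)
        self.b_total = self.b.sum(axis=1)
        self.diff = self.a - self.b
        self.log_prior = -np.log(K + 1)

    def stage_log_likelihoods(self, ordering: np.ndarray) -> np.ndarray:
        """(n, K+1) log likelihood of each subject at each stage."""
        D = self.diff[:, ordering]
        cum = np.concatenate(
            [np.zeros((self.n_subjects, 1)), np.cumsum(D, axis=1)], axis=1
        )
        return cum + self.b_total[:, None]

    def subtype_marginal(self, ordering: np.ndarray) -> np.ndarray:
        """(n,) log sum_s pi(s) P(x | ordering, s)."""
        L = self.stage_log_likelihoods(ordering)
        return logsumexp(L, axis=1) + self.log_prior


def stage_likelihood(f_ab: np.ndarray, f_no: np.ndarray, cluster_ids: np.ndarray,
                     ordering: Sequence[int], stage: int) -> float:
    """Likelihood of one subject's observations at a given stage.

    ``f_ab``/``f_no`` are raw (not log) component densities per feature,
    ``cluster_ids`` the 0-based cluster of each feature and ``ordering``
    a permutation of the clusters. Features in the first ``stage``
    clusters of the ordering contribute their abnormal density, the rest
    their normal density. Intended for small hand-checkable inputs; the
    fitting code uses the log-space :class:`ClusterDensities` instead.
    """
    ordering = np.asarray(ordering, dtype=int)
    K = len(ordering)
    if not 0 <= stage <= K:
        raise ValueError(f"stage must be in 0..{K}")
    abnormal_clusters = set(ordering[:stage].tolist())
    dens = np.where(np.isin(cluster_ids, list(abnormal_clusters)), f_ab, f_no)
    return float(np.prod(dens))


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass
class SubtypeModel:
    """C orderings over K event clusters with mixing fractions."""

    orderings: np.ndarray        # (C, K), 0-based
    fractions: np.ndarray        # (C,)
    stage_prior: np.ndarray      # (K+1,)
    log_likelihood: float = np.nan

    def __post_init__(self):
        self.orderings = np.atleast_2d(np.asarray(self.orderings, dtype=int))
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.stage_prior = np.asarray(self.stage_prior, dtype=float)
        C, K = self.orderings.shape
        if len(self.fractions) != C:
            raise ValueError("fractions/orderings mismatch")
        if abs(self.fractions.sum() - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")
        if abs(self.stage_prior.sum() - 1.0) > 1e-9:
            raise ValueError("stage prior must sum to 1")
        for sigma in self.orderings:
            if sorted(sigma.tolist()) != list(range(K)):
                raise ValueError(f"not a permutation: {sigma}")

    @property
    def n_subtypes(self) -> int:
        return self.orderings.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.orderings.shape[1]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "orderings": (self.orderings + 1).tolist(),   # 1-based externally
            "fractions": self.fractions.tolist(),
            "stage_prior": self.stage_prior.tolist(),
            "log_likelihood": float(self.log_likelihood),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SubtypeModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            np.asarray(doc["orderings"], dtype=int) - 1,
            np.asarray(doc["fractions"], dtype=float),
            np.asarray(doc["stage_prior"], dtype=float),
            doc.get("log_likelihood", np.nan),
        )


@dataclass
class PosteriorSamples:
    """Post-burn-in MCMC draws of (orderings, fractions)."""

    orderings: np.ndarray        # (S, C, K) int16
    fractions: np.ndarray        # (S, C)
    n_total: int
    n_burn_in: int
    n_accepted: int
    seed: int

    def __post_init__(self):
        if self.orderings.shape[0] != self.n_total - self.n_burn_in:
            raise ValueError("stored samples must equal n_total - n_burn_in")

    @property
    def n_samples(self) -> int:
        return self.orderings.shape[0]

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_total

    def to_npz(self, path: str | Path) -> None:  # pragma: no cover - convenience
        np.savez_compressed(
            path, orderings=self.orderings, fractions=self.fractions,
            meta=np.array([self.n_total, self.n_burn_in, self.n_accepted, self.seed]),
        )


@dataclass
class MCMCConfig:
    """Sampler settings; the study-scale preset is 2e6 total draws with
    the first 1e6 discarded."""

    n_total: int = 2_000_000
    n_burn_in: int = 1_000_000
    fraction_step: float = 0.05
    n_restarts: int = 16          # greedy random restarts at C = 1
    n_split_tries: int = 3        # restarts of the hierarchical buildup

    def validate(self):
        if self.n_burn_in >= self.n_total:
            raise ConfigurationError("burn-in must be smaller than total samples")


# ---------------------------------------------------------------------------
# Log-likelihood and fitting
# ---------------------------------------------------------------------------


def _total_loglik(S: np.ndarray, fractions: np.ndarray) -> float:
    """S: (n, C) per-subtype marginals; returns full-data log likelihood."""
    with np.errstate(divide="ignore"):
        lw = np.log(fractions)
    return float(logsumexp(S + lw[None, :], axis=1).sum())


def model_log_likelihood(epm: EventProbabilityMatrix, model: SubtypeModel,
                         clustering: EventClustering) -> float:
    """Marginal log likelihood of the data under a subtype model.

    Computed with log-sum-exp throughout: the result is finite whenever
    every subject has positive likelihood at some (subtype, stage).
    """
    dens = ClusterDensities(epm, clustering)
    S = np.column_stack([dens.subtype_marginal(s) for s in model.orderings])
    return _total_loglik(S, model.fractions)


def _check_finite_init(S: np.ndarray, dens: ClusterDensities) -> None:
    bad = ~np.isfinite(logsumexp(S, axis=1))
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise FitError(
            f"non-finite likelihood at initialisation for subject "
            f"{dens.subject_ids[idx]!r}"
        )


def _em_fractions(S: np.ndarray, fractions: np.ndarray, tol: float = 1e-10,
                  max_iter: int = 500):
    """EM updates of mixing fractions at fixed orderings (monotone)."""
    f = fractions.copy()
    prev = -np.inf
    for _ in range(max_iter):
        with np.errstate(divide="ignore"):
            logw = S + np.log(f)[None, :]
        norm = logsumexp(logw, axis=1, keepdims=True)
        r = np.exp(logw - norm)
        f = r.mean(axis=0)
        f = np.clip(f, 1e-12, None)
        f /= f.sum()
        cur = _total_loglik(S, f)
        if cur - prev < tol:
            break
        prev = cur
    return f, r


def _lex_smaller(a: np.ndarray, b: np.ndarray) -> bool:
    return tuple(a.tolist()) < tuple(b.tolist())


def _neighbours(sigma: np.ndarray):
    """Pairwise swaps plus remove-and-reinsert (insertion) moves.

    Insertions rescue the common local optima of swap-only ascent,
    where restoring a displaced event requires two coordinated swaps
    whose intermediate state is worse.
    """
    K = len(sigma)
    seen = {sigma.tobytes()}
    out = []
    for i, j in itertools.combinations(range(K), 2):
        cand = sigma.copy()
        cand[i], cand[j] = cand[j], cand[i]
        if cand.tobytes() not in seen:
            seen.add(cand.tobytes())
            out.append(cand)
    for i in range(K):
        rest = np.delete(sigma, i)
        for j in range(K):
            if j == i:
                continue
            cand = np.insert(rest, j, sigma[i])
            if cand.tobytes() not in seen:
                seen.add(cand.tobytes())
                out.append(cand)
    return out


def _ascend(dens: ClusterDensities, orderings: np.ndarray, fractions: np.ndarray,
            S: np.ndarray):
    """Coordinate ascent: best-improving swap/insertion moves per
    subtype, alternated with EM fraction updates, until nothing improves.

    Exact likelihood ties are broken toward the lexicographically
    smallest ordering.
    """
    C, K = orderings.shape
    ll = _total_loglik(S, fractions)
    improved = True
    while improved:
        improved = False
        for c in range(C):
            while True:
                best_ll, best_sigma, best_col = ll, None, None
                for sigma in _neighbours(orderings[c]):
                    col = dens.subtype_marginal(sigma)
                    S_try = S.copy()
                    S_try[:, c] = col
                    cand = _total_loglik(S_try, fractions)
                    take = cand > best_ll + _TIE_TOL or (
                        abs(cand - best_ll) <= _TIE_TOL
                        and best_sigma is None
                        and _lex_smaller(sigma, orderings[c])
                    )
                    if take:
                        best_ll, best_sigma, best_col = cand, sigma, col
                if best_sigma is None:
                    break
                orderings[c] = best_sigma
                S[:, c] = best_col
                ll = best_ll
                improved = True
        if C > 1:
            fractions, _ = _em_fractions(S, fractions)
            new_ll = _total_loglik(S, fractions)
            if new_ll > ll + _TIE_TOL:
                improved = True
            ll = new_ll
    return orderings, fractions, S, ll


def _weighted_ordering_fit(dens, weights: np.ndarray, starts,
                           rng: np.random.Generator, n_random: int = 3):
    """Maximise sum_i w_i * log marginal_i(sigma) by greedy neighbourhood
    ascent from the given starting orderings plus random restarts."""
    K = dens.n_clusters
    starts = [np.asarray(s) for s in starts]
    starts += [rng.permutation(K) for _ in range(n_random)]
    best_sigma, best_col, best_obj = None, None, -np.inf
    for sigma in starts:
        sigma = sigma.copy()
        col = dens.subtype_marginal(sigma)
        obj = float(weights @ col)
        while True:
            step_sigma, step_col, step_obj = None, None, obj
            for cand in _neighbours(sigma):
                ccol = dens.subtype_marginal(cand)
                cobj = float(weights @ ccol)
                if cobj > step_obj + 1e-10:
                    step_sigma, step_col, step_obj = cand, ccol, cobj
            if step_sigma is None:
                break
            sigma, col, obj = step_sigma, step_col, step_obj
        if obj > best_obj + 1e-12 or (
            abs(obj - best_obj) <= 1e-12 and best_sigma is not None
            and _lex_smaller(sigma, best_sigma)
        ):
            best_sigma, best_col, best_obj = sigma, col, obj
    return best_sigma, best_col


def _em_orderings(dens: ClusterDensities, orderings, fractions, S,
                  rng: np.random.Generator, max_rounds: int = 25):
    """EM over the latent subtype assignment with a full per-subtype
    ordering refit as the M-step.

    Local swap/insertion ascent optimises one ordering at a time and can
    sit in joint valleys where two orderings must change together; the
    EM surrogate (each subtype's ordering refitted from scratch on its
    responsibility-weighted subjects) escapes those while never
    decreasing the data likelihood.
    """
    C = orderings.shape[0]
    ll = _total_loglik(S, fractions)
    for _ in range(max_rounds):
        with np.errstate(divide="ignore"):
            logw = S + np.log(fractions)[None, :]
        r = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
        changed = False
        for c in range(C):
            sigma, col = _weighted_ordering_fit(
                dens, r[:, c], [orderings[c]], rng)
            if not np.array_equal(sigma, orderings[c]):
                orderings[c] = sigma
                S[:, c] = col
                changed = True
        fractions, _ = _em_fractions(S, fractions)
        new_ll = _total_loglik(S, fractions)
        if not changed and new_ll <= ll + 1e-9:
            ll = new_ll
            break
        ll = new_ll
    return orderings, fractions, S, ll


def _optimise(dens: ClusterDensities, orderings, fractions, S,
              rng: np.random.Generator):
    """Alternate local ascent and EM ordering refits to convergence."""
    orderings, fractions, S, ll = _ascend(dens, orderings, fractions, S)
    if orderings.shape[0] == 1:
        return orderings, fractions, S, ll
    while True:
        orderings, fractions, S, em_ll = _em_orderings(
            dens, orderings, fractions, S, rng)
        orderings, fractions, S, new_ll = _ascend(dens, orderings, fractions, S)
        if new_ll <= ll + 1e-9:
            return orderings, fractions, S, max(new_ll, ll)
        ll = new_ll


def _fit_single(dens: ClusterDensities, rng: np.random.Generator,
                n_restarts: int):
    """Greedy ascent at C = 1 from multiple random starting orderings."""
    K = dens.n_clusters
    best = None
    for _ in range(max(1, n_restarts)):
        sigma = rng.permutation(K)
        o, f, S, ll = _ascend(
            dens, sigma[None, :].copy(), np.array([1.0]),
            dens.subtype_marginal(sigma)[:, None],
        )
        if best is None or ll > best[3] + _TIE_TOL or (
            abs(ll - best[3]) <= _TIE_TOL and _lex_smaller(o[0], best[0][0])
        ):
            best = (o, f, S, ll)
    return best


def _split_candidate(dens: ClusterDensities, orderings, fractions, S, split: int,
                     rng: np.random.Generator, mcmc: "MCMCConfig"):
    """Split one subtype in two and re-optimise the whole model.

    The subtype's hard-assigned subjects are randomly bipartitioned and
    a one-subtype model fitted to each half; the two orderings seed the
    new pair before joint ascent over all orderings and fractions.
    """
    K = dens.n_clusters
    with np.errstate(divide="ignore"):
        logw = S + np.log(fractions)[None, :]
    r = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    members = np.flatnonzero(r.argmax(axis=1) == split)
    copies = []
    if len(members) >= 4:
        half = rng.permutation(members)
        for rows in (half[: len(half) // 2], half[len(half) // 2:]):
            sub = _DensView(dens, rows)
            o, _, _, _ = _fit_single(sub, rng, max(4, mcmc.n_restarts // 2))
            copies.append(o[0])
    else:  # degenerate subtype: fall back to random perturbations
        for _ in range(2):
            sigma = orderings[split].copy()
            i, j = rng.choice(K, size=2, replace=False)
            sigma[i], sigma[j] = sigma[j], sigma[i]
            copies.append(sigma)
    new_o = np.vstack([orderings[:split], copies, orderings[split + 1:]])
    f_s = fractions[split] / 2
    new_f = np.concatenate([fractions[:split], [f_s, f_s], fractions[split + 1:]])
    new_S = np.column_stack([dens.subtype_marginal(s) for s in new_o])
    return _optimise(dens, new_o, new_f, new_S, rng)


def _grow_subtypes(dens: ClusterDensities, base, n_subtypes: int,
                   rng: np.random.Generator, mcmc: "MCMCConfig"):
    """Hierarchical buildup: at each level try splitting *every* current
    subtype in two, re-optimise each candidate model fully, and keep the
    most likely, until the target subtype count is reached."""
    orderings, fractions, S, ll = (base[0].copy(), base[1].copy(),
                                   base[2].copy(), base[3])
    while orderings.shape[0] < n_subtypes:
        best = None
        for split in range(orderings.shape[0]):
            cand = _split_candidate(dens, orderings, fractions, S, split, rng, mcmc)
            if best is None or cand[3] > best[3] + _TIE_TOL:
                best = cand
        orderings, fractions, S, ll = best
    return orderings, fractions, S, ll


class _DensView:
    """Row-subset view of a :class:`ClusterDensities` (for split fits)."""

    def __init__(self, dens: ClusterDensities, rows: np.ndarray):
        self.n_subjects = len(rows)
        self.n_clusters = dens.n_clusters
        self.subject_ids = dens.subject_ids[rows]
        self.b_total = dens.b_total[rows]
        self.diff = dens.diff[rows]
        self.log_prior = dens.log_prior

    stage_log_likelihoods = ClusterDensities.stage_log_likelihoods
    subtype_marginal = ClusterDensities.subtype_marginal


def fit_subtypes(epm: EventProbabilityMatrix, clustering: EventClustering,
                 n_subtypes: int, mcmc: MCMCConfig | None = None,
                 seed: int | None = None):
    """Fit a C-subtype model hierarchically, then sample with MCMC.

    The hierarchical stage fits C = 1 by greedy pairwise-swap ascent over
    orderings (multiple random restarts), then repeatedly splits the
    subtype with the lowest responsibility-weighted average subject log
    likelihood — bipartitioning its hard-assigned subjects and fitting a
    one-subtype model to each half — and re-optimises all orderings and
    fractions until C subtypes exist (the buildup is itself restarted
    ``n_split_tries`` times, keeping the best). Metropolis-Hastings then runs
    from the fitted state, alternating two symmetric-in-practice move
    types — swap two positions in one randomly chosen subtype's
    ordering, or perturb the fractions with renormalised Gaussian
    noise — accepting by likelihood ratio. The
    returned model is the highest-likelihood state ever visited
    (including the greedy initialisation), so the chain can only improve
    on the hierarchical fit.

    Returns (SubtypeModel, PosteriorSamples).
    """
    if seed is None:
        raise ConfigurationError("fit_subtypes is stochastic: a seed is required")
    if n_subtypes < 1:
        raise ConfigurationError("n_subtypes must be >= 1")
    mcmc = mcmc or MCMCConfig()
    mcmc.validate()
    rng = np.random.default_rng(seed)
    dens = ClusterDensities(epm, clustering)
    K = dens.n_clusters

    base = _fit_single(dens, rng, mcmc.n_restarts)
    _check_finite_init(base[2], dens)
    best_state = None
    for _ in range(max(1, mcmc.n_split_tries)):
        state = _grow_subtypes(dens, base, n_subtypes, rng, mcmc)
        if best_state is None or state[3] > best_state[3] + _TIE_TOL:
            best_state = state
    orderings, fractions, S, ll = best_state

    C = orderings.shape[0]
    stage_prior = np.full(K + 1, 1.0 / (K + 1))

    # ---- Metropolis-Hastings over (orderings, fractions) ---------------
    n_store = mcmc.n_total - mcmc.n_burn_in
    stored_orderings = np.empty((n_store, C, K), dtype=np.int16)
    stored_fractions = np.empty((n_store, C))
    cur_o, cur_f, cur_S, cur_ll = orderings.copy(), fractions.copy(), S.copy(), ll
    best_o, best_f, best_ll = cur_o.copy(), cur_f.copy(), cur_ll
    n_accepted = 0
    for it in range(mcmc.n_total):
        # alternate move types: fraction-only perturbations keep the chain
        # mixing even when the data pin the orderings down sharply
        if C > 1 and rng.random() < 0.5:
            prop_f = cur_f + rng.normal(0.0, mcmc.fraction_step, C)
            prop_f = np.clip(prop_f, 1e-9, None)
            prop_f /= prop_f.sum()
            prop_ll = _total_loglik(cur_S, prop_f)
            if np.log(rng.random()) < prop_ll - cur_ll:
                cur_f, cur_ll = prop_f, prop_ll
                n_accepted += 1
        else:
            c = int(rng.integers(C))
            i, j = rng.choice(K, size=2, replace=False)
            prop_sigma = cur_o[c].copy()
            prop_sigma[i], prop_sigma[j] = prop_sigma[j], prop_sigma[i]
            S_prop = cur_S.copy()
            S_prop[:, c] = dens.subtype_marginal(prop_sigma)
            prop_ll = _total_loglik(S_prop, cur_f)
            if np.log(rng.random()) < prop_ll - cur_ll:
                cur_o = cur_o.copy()
                cur_o[c] = prop_sigma
                cur_S, cur_ll = S_prop, prop_ll
                n_accepted += 1
        if cur_ll > best_ll:
            best_o, best_f, best_ll = cur_o.copy(), cur_f.copy(), cur_ll
        if it >= mcmc.n_burn_in:
            stored_orderings[it - mcmc.n_burn_in] = cur_o
            stored_fractions[it - mcmc.n_burn_in] = cur_f

    samples = PosteriorSamples(
        stored_orderings, stored_fractions, mcmc.n_total, mcmc.n_burn_in,
        n_accepted, seed,
    )
    model = SubtypeModel(best_o, best_f, stage_prior, best_ll)
    return model, samples


def select_subtype_count(epm: EventProbabilityMatrix, clustering: EventClustering,
                         candidates: Sequence[int], mcmc: MCMCConfig | None = None,
                         seed: int | None = None, tie_tol: float = 1e-6,
                         return_fits: bool = False):
    """Fit every candidate subtype count and pick the most likely.

    Counts whose fitted log likelihood is within ``tie_tol`` of the best
    are treated as ties, resolved toward the smaller count.
    """
    if not candidates:
        raise ConfigurationError("candidates must be non-empty")
    if seed is None:
        raise ConfigurationError("selection is stochastic: a seed is required")
    fits = {}
    child = np.random.SeedSequence(seed).generate_state(len(candidates)) % (2**31)
    for c, s in zip(candidates, child):
        fits[int(c)] = fit_subtypes(epm, clustering, int(c), mcmc, int(s))
    best_ll = max(m.log_likelihood for m, _ in fits.values())
    selected = min(
        c for c, (m, _) in fits.items() if m.log_likelihood >= best_ll - tie_tol
    )
    return (selected, fits) if return_fits else selected


# ---------------------------------------------------------------------------
# Estimator facade
# ---------------------------------------------------------------------------


class SubtypeStagingModel(BaseEstimator):
    """Subtype/stage inference as a scikit-learn style estimator.

    Parameters mirror the study-scale defaults: 5 event clusters
    (minimum size 8), subtype counts compared over {2, 3, 4}, and an
    MCMC schedule of 2e6 total / 1e6 burn-in draws (scale these down for
    interactive work). ``random_state`` is required: every stochastic
    step refuses to run unseeded.

    After ``fit``: ``clustering_``, ``model_``, ``posterior_``,
    ``n_subtypes_``, ``log_likelihood_``, ``candidate_log_likelihoods_``.
    ``predict`` returns an (n, 2) array of [subtype (1-based), stage];
    ``predict_proba`` the averaged joint posterior of shape (n, C, K+1).
    """

    def __init__(self, n_clusters: int = 5, min_cluster_size: int = 8,
                 n_subtypes=(2, 3, 4), n_mcmc: int = 2_000_000,
                 n_burn_in: int = 1_000_000, n_draw: int = 1_000,
                 n_restarts: int = 16, fraction_step: float = 0.05,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.min_cluster_size = min_cluster_size
        self.n_subtypes = n_subtypes
        self.n_mcmc = n_mcmc
        self.n_burn_in = n_burn_in
        self.n_draw = n_draw
        self.n_restarts = n_restarts
        self.fraction_step = fraction_step
        self.random_state = random_state

    def _mcmc_config(self) -> MCMCConfig:
        return MCMCConfig(self.n_mcmc, self.n_burn_in,
                          self.fraction_step, self.n_restarts)

    def fit(self, X: EventProbabilityMatrix, y=None):
        if self.random_state is None:
            raise ConfigurationError("random_state is required")
        self.clustering_ = cluster_events(X, self.n_clusters, self.min_cluster_size)
        cfg = self._mcmc_config()
        if np.isscalar(self.n_subtypes):
            cands: Sequence[int] = [int(self.n_subtypes)]
        else:
            cands = [int(c) for c in self.n_subtypes]
        selected, fits = select_subtype_count(
            X, self.clustering_, cands, cfg, self.random_state, return_fits=True
        )
        self.n_subtypes_ = selected
        self.model_, self.posterior_ = fits[selected]
        self.candidate_log_likelihoods_ = {
            c: m.log_likelihood for c, (m, _) in fits.items()
        }
        self.log_likelihood_ = self.model_.log_likelihood
        return self

    def score(self, X: EventProbabilityMatrix, y=None) -> float:
        return model_log_likelihood(X, self.model_, self.clustering_)

    def predict_proba(self, X: EventProbabilityMatrix) -> np.ndarray:
        from .assign import assign_subjects
        assignments = assign_subjects(
            X, self.clustering_, self.posterior_, n_draw=self.n_draw,
            seed=self.random_state,
        )
        return np.stack([a.posterior for a in assignments])

    def predict(self, X: EventProbabilityMatrix) -> np.ndarray:
        from .assign import assign_subjects
        assignments = assign_subjects(
            X, self.clustering_, self.posterior_, n_draw=self.n_draw,
            seed=self.random_state,
        )
        return np.array([[a.subtype, a.stage] for a in assignments])
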