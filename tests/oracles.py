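"""Independent brute-force reference implementations.

Everything here is deliberately written with plain Python loops and
direct formulas, sharing no code with the package's vectorised
log-space implementations, so the two can serve as cross-checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def naive_stage_likelihood(f_ab, f_no, cluster_ids, ordering, stage):
    """Direct product: abnormal density for features whose cluster is
    among the first `stage` entries of the ordering, normal otherwise."""
    flipped = set(int(c) for c in ordering[:stage])
    out = 1.0
    for j in range(len(cluster_ids)):
        out *= f_ab[j] if int(cluster_ids[j]) in flipped else f_no[j]
    return out


def naive_subject_likelihood(log_ab_row, log_no_row, cluster_ids, orderings,
                             fractions):
    """sum_c f_c sum_s pi(s) * stage likelihood, via exp of summed logs."""
    K = len(orderings[0])
    pi = 1.0 / (K + 1)
    total = 0.0
    for sigma, f in zip(orderings, fractions):
        for s in range(K + 1):
            flipped = set(int(c) for c in sigma[:s])
            logl = 0.0
            for j in range(len(cluster_ids)):
                logl += log_ab_row[j] if int(cluster_ids[j]) in flipped else log_no_row[j]
            total += f * pi * math.exp(logl)
    return total


def naive_model_loglik(log_ab, log_no, cluster_ids, orderings, fractions):
    return sum(
        math.log(naive_subject_likelihood(log_ab[i], log_no[i], cluster_ids,
                                          orderings, fractions))
        for i in range(log_ab.shape[0])
    )


def em_fractions_naive(subject_stage_sums, fractions, n_iter=2000):
    """EM for mixing fractions with per-(subject, subtype) likelihoods
    already marginalised over stages. subject_stage_sums: (n, C) plain
    likelihood values (not logs)."""
    f = np.asarray(fractions, dtype=float).copy()
    for _ in range(n_iter):
        w = subject_stage_sums * f[None, :]
        w = w / w.sum(axis=1, keepdims=True)
        new = w.mean(axis=0)
        if np.max(np.abs(new - f)) < 1e-14:
            f = new
            break
        f = new
    return f


def exhaustive_ml_fit(log_ab, log_no, cluster_ids, n_subtypes):
    """Enumerate every combination of orderings (K!^C), optimise the
    fractions by EM for each, and return the best.

    Only feasible for tiny K, C, n. Returns (best orderings tuple,
    best fractions, best log-likelihood).
    """
    K = len(set(int(c) for c in cluster_ids))
    n = log_ab.shape[0]
    perms = list(itertools.permutations(range(K)))
    pi = 1.0 / (K + 1)

    def stage_sums(sigma):
        col = np.empty(n)
        for i in range(n):
            tot = 0.0
            for s in range(K + 1):
                flipped = set(sigma[:s])
                logl = 0.0
                for j in range(len(cluster_ids)):
                    logl += log_ab[i, j] if int(cluster_ids[j]) in flipped else log_no[i, j]
                tot += pi * math.exp(logl)
            col[i] = tot
        return col

    cache = {sigma: stage_sums(sigma) for sigma in perms}
    best = None
    for combo in itertools.product(perms, repeat=n_subtypes):
        M = np.column_stack([cache[sigma] for sigma in combo])
        f = em_fractions_naive(M, np.full(n_subtypes, 1.0 / n_subtypes))
        ll = float(np.log(M @ f).sum())
        if best is None or ll > best[2] + 1e-12:
            best = (combo, f, ll)
    return best
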