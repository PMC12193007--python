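"""Progression model: clustering, likelihood, fitting, subtype selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau
from sklearn.metrics import adjusted_rand_score

from substage import (ConfigurationError, EventClustering, MCMCConfig,
                      SubtypeModel, cluster_events, default_study_config,
                      fit_subtypes, generate_cohort, model_log_likelihood,
                      ordering_recovery, select_subtype_count, stage_likelihood)
from substage.model import ClusterDensities
from substage.preprocess import EventMixturePreprocessor

from oracles import (exhaustive_ml_fit, naive_model_loglik,
                     naive_stage_likelihood)

SMALL_MCMC = MCMCConfig(n_total=4000, n_burn_in=2000, n_restarts=8,
                        n_split_tries=2)


def _blocky_epm(epm_factory, n=300, k=5, per=6, rho=0.9, seed=0):
    """Features in k blocks sharing a latent binary state (correlation
    ~rho within a block, ~0 between)."""
    rng = np.random.default_rng(seed)
    z = rng.integers(0, 2, (n, k)).astype(float)
    cols = []
    labels = []
    for b in range(k):
        for _ in range(per):
            noisy = np.where(rng.random(n) < (1 - rho) / 2, 1 - z[:, b], z[:, b])
            cols.append(noisy * 4.0 - 2.0)
            labels.append(b)
    log_ab = np.column_stack(cols)
    return log_ab, np.zeros_like(log_ab), np.array(labels)


class TestClustering:
    def test_recovers_planted_blocks_exactly(self, epm_factory):
        log_ab, log_no, labels = _blocky_epm(epm_factory)
        epm = epm_factory(log_ab, log_no)
        cl = cluster_events(epm, 5, min_cluster_size=2)
        assert adjusted_rand_score(labels, cl.labels) == 1.0

    def test_singleton_clusters_when_k_equals_features(self, epm_factory):
        rng = np.random.default_rng(1)
        epm = epm_factory(rng.normal(size=(50, 6)), rng.normal(size=(50, 6)))
        cl = cluster_events(epm, 6, min_cluster_size=1)
        assert sorted(cl.labels) == list(range(6))

    def test_study_scale_clustering_sizes(self, paper_epm_train):
        cl = cluster_events(paper_epm_train, 5, min_cluster_size=8)
        assert cl.n_clusters == 5
        assert (cl.sizes >= 8).all()
        assert cl.sizes.sum() == 118

    def test_infeasible_min_size_raises(self, epm_factory):
        rng = np.random.default_rng(2)
        epm = epm_factory(rng.normal(size=(30, 6)), rng.normal(size=(30, 6)))
        with pytest.raises(ConfigurationError):
            cluster_events(epm, 3, min_cluster_size=4)

    def test_undersized_clusters_get_merged(self, epm_factory):
        # one tight pair of features plus three blocks: min size forces a merge
        log_ab, log_no, labels = _blocky_epm(epm_factory, k=4, per=5)
        extra = log_ab[:, :1] * 0.97  # near-duplicate of block 0's first feature
        epm = epm_factory(np.hstack([log_ab, extra]),
                          np.hstack([log_no, extra * 0.0]))
        cl = cluster_events(epm, 4, min_cluster_size=5)
        assert (cl.sizes >= 5).all()


class TestStageLikelihood:
    def test_boundary_stages(self):
        f_ab = np.array([0.2, 0.3, 0.5])
        f_no = np.array([0.9, 0.8, 0.7])
        cluster_ids = np.array([0, 1, 2])
        assert stage_likelihood(f_ab, f_no, cluster_ids, [0, 1, 2], 0) == (
            pytest.approx(0.9 * 0.8 * 0.7))
        assert stage_likelihood(f_ab, f_no, cluster_ids, [0, 1, 2], 3) == (
            pytest.approx(0.2 * 0.3 * 0.5))

    def test_matches_hand_multiplied_toy_value(self):
        rng = np.random.default_rng(3)
        f_ab = rng.uniform(0.05, 1.0, 7)
        f_no = rng.uniform(0.05, 1.0, 7)
        cluster_ids = np.array([0, 0, 1, 1, 2, 2, 2])
        for sigma in itertools.permutations(range(3)):
            for s in range(4):
                mine = stage_likelihood(f_ab, f_no, cluster_ids, sigma, s)
                ref = naive_stage_likelihood(f_ab, f_no, cluster_ids, sigma, s)
                assert abs(mine - ref) < 1e-12


class TestModelLogLikelihood:
    @pytest.fixture
    def toy(self, epm_factory):
        rng = np.random.default_rng(4)
        log_ab = rng.normal(-1, 0.5, (2, 4))
        log_no = rng.normal(-1, 0.5, (2, 4))
        epm = epm_factory(log_ab, log_no)
        cl = EventClustering([f"f{j}" for j in range(4)], [0, 0, 1, 1], 2, 1)
        return epm, cl, log_ab, log_no

    def test_equals_bruteforce_enumeration(self, toy):
        epm, cl, log_ab, log_no = toy
        model = SubtypeModel([[0, 1]], [1.0], [1 / 3] * 3)
        mine = model_log_likelihood(epm, model, cl)
        ref = naive_model_loglik(log_ab, log_no, cl.labels, [(0, 1)], [1.0])
        assert mine == pytest.approx(ref, abs=1e-10)

    def test_subject_duplication_doubles_loglik(self, toy, epm_factory):
        epm, cl, log_ab, log_no = toy
        model = SubtypeModel([[0, 1], [1, 0]], [0.6, 0.4], [1 / 3] * 3)
        double = epm_factory(np.vstack([log_ab, log_ab]),
                             np.vstack([log_no, log_no]))
        assert model_log_likelihood(double, model, cl) == pytest.approx(
            2 * model_log_likelihood(epm, model, cl), rel=1e-12)

    def test_invariant_under_subtype_relabelling(self, toy):
        epm, cl, *_ = toy
        a = SubtypeModel([[0, 1], [1, 0]], [0.7, 0.3], [1 / 3] * 3)
        b = SubtypeModel([[1, 0], [0, 1]], [0.3, 0.7], [1 / 3] * 3)
        assert model_log_likelihood(epm, a, cl) == pytest.approx(
            model_log_likelihood(epm, b, cl), rel=1e-12)

    def test_finite_under_extreme_underflow(self, epm_factory):
        epm = epm_factory(np.full((3, 4), -650.0), np.full((3, 4), -700.0))
        cl = EventClustering([f"f{j}" for j in range(4)], [0, 0, 1, 1], 2, 1)
        model = SubtypeModel([[0, 1]], [1.0], [1 / 3] * 3)
        assert np.isfinite(model_log_likelihood(epm, model, cl))


def _planted_epm(epm_factory, orderings, fractions, n, effect=2.0, seed=0):
    """Cluster-level planted data: each subject has a subtype, a uniform
    stage and per-cluster log densities favouring the true state."""
    rng = np.random.default_rng(seed)
    orderings = np.asarray(orderings)
    C, K = orderings.shape
    subtypes = rng.choice(C, n, p=fractions)
    stages = rng.integers(0, K + 1, n)
    per = 3  # features per cluster
    log_ab = np.empty((n, K * per))
    log_no = np.empty((n, K * per))
    labels = np.repeat(np.arange(K), per)
    pos = np.empty((C, K), dtype=int)
    for c in range(C):
        pos[c, orderings[c]] = np.arange(K)
    for i in range(n):
        abnormal = pos[subtypes[i]] < stages[i]
        for j in range(K * per):
            x = rng.normal(effect if abnormal[labels[j]] else 0.0, 1.0)
            log_ab[i, j] = -0.5 * (x - effect) ** 2
            log_no[i, j] = -0.5 * x ** 2
    cl = EventClustering([f"f{j}" for j in range(K * per)], labels, K, 1)
    return epm_factory(log_ab, log_no), cl, subtypes, stages


class TestFitSubtypes:
    def test_seed_is_mandatory(self, epm_factory):
        epm, cl, *_ = _planted_epm(epm_factory, [[0, 1, 2]], [1.0], 20)
        with pytest.raises(ConfigurationError, match="seed"):
            fit_subtypes(epm, cl, 1, SMALL_MCMC)

    def test_single_subtype_greedy_matches_exhaustive(self, epm_factory):
        epm, cl, *_ = _planted_epm(
            epm_factory, [[2, 0, 1]], [1.0], 40, effect=1.5, seed=5)
        model, _ = fit_subtypes(epm, cl, 1, SMALL_MCMC, seed=5)
        combo, f, best_ll = exhaustive_ml_fit(epm.log_f_ab, epm.log_f_no,
                                              cl.labels, 1)
        assert tuple(model.orderings[0]) == combo[0]
        assert model.log_likelihood == pytest.approx(best_ll, abs=1e-6)

    def test_two_subtype_fit_matches_exhaustive_enumeration(self, epm_factory):
        """Oracle equivalence at K=3, C=2, n=12: fitted likelihood and
        orderings agree with enumeration over all (3!)^2 combinations."""
        epm, cl, *_ = _planted_epm(
            epm_factory, [[0, 1, 2], [2, 1, 0]], [0.5, 0.5], 12,
            effect=2.5, seed=6)
        model, _ = fit_subtypes(epm, cl, 2, SMALL_MCMC, seed=6)
        combo, f, best_ll = exhaustive_ml_fit(epm.log_f_ab, epm.log_f_no,
                                              cl.labels, 2)
        assert model.log_likelihood == pytest.approx(best_ll, abs=1e-6)
        # the fitted orderings attain the exhaustive maximum (argmax may
        # be non-unique when one mixture component is nearly empty)
        fitted_ll = naive_model_loglik(
            epm.log_f_ab, epm.log_f_no, cl.labels,
            [tuple(s) for s in model.orderings], model.fractions)
        assert fitted_ll == pytest.approx(best_ll, abs=1e-6)

    def test_reversed_orderings_recovered_exactly(self, epm_factory):
        epm, cl, *_ = _planted_epm(
            epm_factory, [[0, 1, 2, 3, 4], [4, 3, 2, 1, 0]], [0.5, 0.5],
            600, effect=2.0, seed=7)
        mcmc = MCMCConfig(n_total=20000, n_burn_in=10000)
        model, post = fit_subtypes(epm, cl, 2, mcmc, seed=7)
        got = {tuple(s) for s in model.orderings}
        assert got == {(0, 1, 2, 3, 4), (4, 3, 2, 1, 0)}
        assert np.allclose(model.fractions, [0.5, 0.5], atol=0.08)

    def test_mcmc_sanity_and_elitism(self, epm_factory):
        epm, cl, *_ = _planted_epm(
            epm_factory, [[0, 1, 2, 3], [3, 2, 1, 0]], [0.5, 0.5], 120,
            effect=1.0, seed=8)
        model, post = fit_subtypes(epm, cl, 2, SMALL_MCMC, seed=8)
        assert 0.0 < post.acceptance_rate < 1.0
        assert post.n_samples == SMALL_MCMC.n_total - SMALL_MCMC.n_burn_in
        # fractions stay on the simplex for every stored sample
        np.testing.assert_allclose(post.fractions.sum(axis=1), 1.0, atol=1e-9)
        assert (post.fractions >= 0).all()
        # elitism: no stored sample beats the returned model
        sample_lls = [
            model_log_likelihood(
                epm,
                SubtypeModel(post.orderings[m].astype(int),
                             post.fractions[m] / post.fractions[m].sum(),
                             model.stage_prior),
                cl)
            for m in range(0, post.n_samples, 400)
        ]
        assert model.log_likelihood >= max(sample_lls) - 1e-9
        assert np.isclose(model.stage_prior.sum(), 1.0)


class TestSelectSubtypeCount:
    def test_single_candidate_returned_without_comparison(self, epm_factory):
        epm, cl, *_ = _planted_epm(epm_factory, [[0, 1, 2]], [1.0], 30)
        assert select_subtype_count(epm, cl, [3], SMALL_MCMC, seed=1) == 3

    def test_exact_tie_prefers_smaller_count(self, epm_factory):
        # uninformative data: every ordering/stage has identical likelihood,
        # so all candidate counts tie exactly and the smaller wins
        epm = epm_factory(np.full((15, 6), -1.0), np.full((15, 6), -1.0))
        cl = EventClustering([f"f{j}" for j in range(6)],
                             [0, 0, 1, 1, 2, 2], 3, 1)
        sel, fits = select_subtype_count(epm, cl, [1, 2], SMALL_MCMC, seed=2,
                                         return_fits=True)
        ll1 = fits[1][0].log_likelihood
        ll2 = fits[2][0].log_likelihood
        assert abs(ll1 - ll2) < 1e-6
        assert sel == 1

    def test_empty_candidates_rejected(self, epm_factory):
        epm, cl, *_ = _planted_epm(epm_factory, [[0, 1, 2]], [1.0], 10)
        with pytest.raises(ConfigurationError):
            select_subtype_count(epm, cl, [], SMALL_MCMC, seed=1)


class TestOrderingRecoveryInvariant:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_mean_kendall_tau_at_least_09(self, seed):
        """Planted orderings are recovered (mean tau >= 0.9) from a
        stage-spanning arm with >= 250 subjects per subtype."""
        cfg = default_study_config().replace(
            seed=seed, effect_size=2.0, n_cn=300, n_ad=200, n_mci=1000,
            subtype_fractions=(0.25,) * 4)
        train, mci, _, _, truth = generate_cohort(cfg)
        pre = EventMixturePreprocessor().fit(train)
        cl = cluster_events(pre.transform(train), 5, 8)
        mcmc = MCMCConfig(n_total=20000, n_burn_in=10000)
        model, _ = fit_subtypes(pre.transform(mci), cl, 4, mcmc, seed=seed)
        rec = ordering_recovery(model, cl, truth)
        assert rec.mean_kendall_tau >= 0.9
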