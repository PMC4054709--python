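"""Unit and property tests for the Gaussian HMM core."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vigilhmm import hmm_core as hc
from vigilhmm.hmm_core import GaussianHMM, InputError, ModelError

from conftest import (
    brute_force_gamma,
    brute_force_loglik,
    brute_force_viterbi,
    gaussian_logpdf,
    random_model,
)


class TestModelValidation:
    def test_rejects_non_stochastic_transition(self):
        with pytest.raises(ModelError):
            GaussianHMM(
                transition=[[0.5, 0.4], [0.5, 0.5]],
                means=[[0.0], [1.0]],
                covariances=np.array([np.eye(1), np.eye(1)]),
                initial=[0.5, 0.5],
            )

    def test_rejects_non_positive_definite_covariance(self):
        with pytest.raises(ModelError):
            GaussianHMM(
                transition=[[1.0]],
                means=[[0.0, 0.0]],
                covariances=np.array([[[1.0, 2.0], [2.0, 1.0]]]),
                initial=[1.0],
            )

    def test_serialization_roundtrip_bit_exact(self, rng):
        m = random_model(rng, 3, 2)
        m2 = GaussianHMM.from_json(m.to_json())
        assert m2 == m

    def test_serialization_rejects_unknown_format(self):
        doc = {"format_version": "bogus"}
        with pytest.raises(InputError):
            GaussianHMM.from_dict(doc)


class TestEmissionDensity:
    def test_standard_normal_at_mode(self):
        m = GaussianHMM([[1.0]], [[0.0]], np.array([np.eye(1)]), [1.0])
        val = hc.emission_logdensity(m, np.array([0.0]))[0]
        assert val == pytest.approx(math.log(1 / math.sqrt(2 * math.pi)), abs=1e-12)

    def test_bivariate_standard_normal_at_mode(self):
        m = GaussianHMM([[1.0]], [[0.0, 0.0]], np.array([np.eye(2)]), [1.0])
        val = hc.emission_logdensity(m, np.zeros(2))[0]
        assert val == pytest.approx(-math.log(2 * math.pi), abs=1e-12)

    def test_matches_direct_density_formula_per_state(self):
        m = GaussianHMM(
            transition=[[0.5, 0.5], [0.5, 0.5]],
            means=[[-1.0], [3.0]],
            covariances=np.array([[[0.25]], [[4.0]]]),
            initial=[0.5, 0.5],
        )
        x = np.array([1.0])
        got = hc.emission_logdensity(m, x)
        for j, (mu, var) in enumerate([(-1.0, 0.25), (3.0, 4.0)]):
            expected = -0.5 * (math.log(2 * math.pi * var) + (1.0 - mu) ** 2 / var)
            assert got[j] == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_raises(self, rng):
        m = random_model(rng, 2, 2)
        with pytest.raises(InputError):
            hc.emission_logdensity(m, np.zeros(3))


class TestLikelihood:
    def test_single_state_chain_is_sum_of_emissions(self, rng):
        m = random_model(rng, 1, 2)
        seq = rng.normal(size=(7, 2))
        expected = sum(
            gaussian_logpdf(x, m.means[0], m.covariances[0]) for x in seq
        )
        assert hc.log_likelihood(m, seq) == pytest.approx(expected, rel=1e-10)

    def test_matches_exhaustive_path_sum(self, rng):
        m = random_model(rng, 2, 1)
        seq = rng.normal(size=(3, 1))
        expected = brute_force_loglik(m, seq)
        assert hc.log_likelihood(m, seq) == pytest.approx(expected, rel=1e-8)

    @pytest.mark.parametrize("G,k,L", [(2, 1, 4), (3, 2, 5), (1, 1, 3)])
    def test_forward_equals_backward(self, rng, G, k, L):
        m = random_model(rng, G, k)
        seq = rng.normal(size=(L, k))
        f = hc.log_likelihood(m, seq, method="forward")
        b = hc.log_likelihood(m, seq, method="backward")
        assert f == pytest.approx(b, abs=1e-8)

    def test_empty_sequence_raises(self, rng):
        m = random_model(rng, 2, 1)
        with pytest.raises(InputError):
            hc.log_likelihood(m, np.empty((0, 1)))


class TestPosteriors:
    def test_single_state_gamma_all_ones(self, rng):
        m = random_model(rng, 1, 1)
        gamma, xi = hc.posteriors(m, rng.normal(size=(5, 1)))
        assert np.allclose(gamma, 1.0)

    def test_absorbing_start_state(self, rng):
        m = GaussianHMM(
            transition=np.eye(2),
            means=[[-5.0], [5.0]],
            covariances=np.array([np.eye(1), np.eye(1)]),
            initial=[1.0, 0.0],
        )
        seq = rng.normal(-5.0, 1.0, size=(6, 1))
        gamma, _ = hc.posteriors(m, seq)
        assert np.allclose(gamma[:, 0], 1.0)

    def test_gamma_matches_brute_force_marginalisation(self, rng):
        m = random_model(rng, 2, 1)
        seq = rng.normal(size=(3, 1))
        gamma, _ = hc.posteriors(m, seq)
        assert np.allclose(gamma, brute_force_gamma(m, seq), atol=1e-8)

    def test_normalisation_and_xi_marginals(self, rng):
        m = random_model(rng, 3, 2)
        seq = rng.normal(size=(6, 2))
        gamma, xi = hc.posteriors(m, seq)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(xi.sum(axis=(1, 2)), 1.0, atol=1e-9)
        assert np.allclose(xi.sum(axis=2), gamma[:-1], atol=1e-8)


class TestViterbi:
    def test_single_state_constant_path(self, rng):
        m = random_model(rng, 1, 1)
        path, _ = hc.viterbi(m, rng.normal(size=(4, 1)))
        assert np.all(path.states == 0)

    def test_matches_exhaustive_argmax(self, rng):
        for _ in range(5):
            m = random_model(rng, 2, 1)
            seq = rng.normal(size=(5, 1))
            path, lj = hc.viterbi(m, seq)
            bpath, blj = brute_force_viterbi(m, seq)
            assert tuple(path.states) == bpath
            assert lj == pytest.approx(blj, abs=1e-8)

    def test_forbidden_transitions_pin_the_path(self, rng):
        m = GaussianHMM(
            transition=np.eye(2),
            means=[[0.0], [0.0]],
            covariances=np.array([np.eye(1), np.eye(1)]),
            initial=[0.0, 1.0],
        )
        path, _ = hc.viterbi(m, rng.normal(size=(8, 1)))
        assert np.all(path.states == 1)

    def test_joint_bounded_by_total_likelihood(self, rng):
        m = random_model(rng, 3, 1)
        seq = rng.normal(size=(6, 1))
        _, lj = hc.viterbi(m, seq)
        assert lj <= hc.log_likelihood(m, seq) + 1e-10


class TestKMeansInit:
    def test_single_cluster_is_pooled_moments(self, rng):
        seqs = [rng.normal(size=(40, 2)), rng.normal(size=(30, 2))]
        m = hc.kmeans_init(seqs, 1, seed=0)
        X = np.vstack(seqs)
        assert np.allclose(m.means[0], X.mean(axis=0), atol=1e-8)
        expected_cov = np.cov(X, rowvar=False, bias=True) + 1e-6 * np.eye(2)
        assert np.allclose(m.covariances[0], expected_cov, atol=1e-8)

    def test_separated_clouds_recovered(self, rng):
        a = rng.normal(-5.0, 1.0, size=(200, 1))
        b = rng.normal(5.0, 1.0, size=(200, 1))
        seqs = [np.vstack([a, b])]
        m = hc.kmeans_init(seqs, 2, seed=3)
        centers = np.sort(m.means[:, 0])
        assert abs(centers[0] + 5.0) < 0.1
        assert abs(centers[1] - 5.0) < 0.1

    def test_deterministic_under_seed(self, rng):
        seqs = [rng.normal(size=(50, 2))]
        m1 = hc.kmeans_init(seqs, 3, seed=11)
        m2 = hc.kmeans_init(seqs, 3, seed=11)
        assert m1 == m2

    def test_too_few_frames_raises(self):
        with pytest.raises(InputError):
            hc.kmeans_init([np.zeros((2, 1))], 3, seed=0)


class TestFitEM:
    def test_recovers_known_two_state_model(self, two_state_1d):
        seqs = [hc.sample(two_state_1d, 200, 100 + i)[1] for i in range(20)]
        m, trace = hc.fit_em(seqs, 2, seed=1)
        order = np.argsort(m.means[:, 0])
        m = m.permuted(order)
        assert np.allclose(m.means, two_state_1d.means, atol=0.2)
        assert np.allclose(m.transition, two_state_1d.transition, atol=0.05)
        assert np.all(np.diff(trace.log_likelihoods) >= -1e-6)

    def test_single_state_closed_form(self, rng):
        seqs = [rng.normal(size=(30, 2)), rng.normal(size=(25, 2))]
        m, trace = hc.fit_em(seqs, 1, seed=0)
        X = np.vstack(seqs)
        assert np.allclose(m.means[0], X.mean(axis=0), atol=1e-9)
        expected = np.cov(X, rowvar=False, bias=True) + 1e-6 * np.eye(2)
        assert np.allclose(m.covariances[0], expected, atol=1e-9)
        assert trace.converged and trace.n_iter <= 2

    def test_trace_monotone_on_random_data(self, rng):
        seqs = [rng.normal(size=(40, 2)) for _ in range(3)]
        _, trace = hc.fit_em(seqs, 3, seed=5, max_iter=30)
        assert np.all(np.diff(trace.log_likelihoods) >= -1e-6)

    def test_diagonal_covariance_option(self, rng):
        seqs = [rng.normal(size=(60, 2))]
        m, _ = hc.fit_em(seqs, 2, seed=2, cov_type="diag")
        for cov in m.covariances:
            assert np.allclose(cov, np.diag(np.diag(cov)))


class TestSample:
    def test_absorbing_start_gives_constant_path(self):
        m = GaussianHMM(
            transition=np.eye(2),
            means=[[0.0], [5.0]],
            covariances=np.array([np.eye(1), np.eye(1)]),
            initial=[1.0, 0.0],
        )
        path, _ = hc.sample(m, 50, seed=0)
        assert np.all(path.states == 0)

    def test_state_frequencies_match_stationary_distribution(self, two_state_1d):
        L = 10000
        path, _ = hc.sample(two_state_1d, L, seed=7)
        stat = hc.stationary_distribution(two_state_1d.transition)
        freq = np.bincount(path.states, minlength=2) / L
        # 3 standard errors with serial correlation inflation left generous
        se = np.sqrt(stat * (1 - stat) / L) * np.sqrt(10)
        assert np.all(np.abs(freq - stat) < 3 * se)

    def test_emission_means_match_per_state(self, two_state_1d):
        path, seq = hc.sample(two_state_1d, 10000, seed=9)
        for j in range(2):
            sel = seq[path.states == j, 0]
            se = 1.0 / np.sqrt(len(sel))
            assert abs(sel.mean() - two_state_1d.means[j, 0]) < 3 * se

    def test_reproducible_under_seed(self, two_state_1d):
        p1, s1 = hc.sample(two_state_1d, 100, seed=3)
        p2, s2 = hc.sample(two_state_1d, 100, seed=3)
        assert np.array_equal(p1.states, p2.states)
        assert np.array_equal(s1, s2)


class TestStatePermutationInvariance:
    def test_likelihood_invariant_and_outputs_permute(self, rng):
        m = random_model(rng, 3, 2)
        seq = rng.normal(size=(6, 2))
        perm = [2, 0, 1]
        mp = m.permuted(perm)
        assert hc.log_likelihood(mp, seq) == pytest.approx(
            hc.log_likelihood(m, seq), rel=1e-10
        )
        gamma, _ = hc.posteriors(m, seq)
        gamma_p, _ = hc.posteriors(mp, seq)
        assert np.allclose(gamma_p, gamma[:, perm], atol=1e-10)
        path, lj = hc.viterbi(m, seq)
        path_p, lj_p = hc.viterbi(mp, seq)
        inv = np.argsort(perm)
        assert np.array_equal(inv[path.states], path_p.states)
        assert lj_p == pytest.approx(lj, abs=1e-10)

    def test_roundtrip_sample_then_fit(self, two_state_1d):
        """Sampling from a model and refitting recovers it up to relabelling."""
        seqs = [hc.sample(two_state_1d, 150, 200 + i)[1] for i in range(15)]
        m, _ = hc.fit_em(seqs, 2, seed=4)
        m = m.permuted(np.argsort(m.means[:, 0]))
        assert np.allclose(m.means, two_state_1d.means, atol=0.3)
        assert np.allclose(m.transition, two_state_1d.transition, atol=0.07)


class TestPropertyInvariants:
    """Model-agnostic invariants over randomly generated instances."""

    @given(
        seed=st.integers(0, 2**31 - 1),
        G=st.integers(1, 3),
        k=st.integers(1, 2),
        L=st.integers(1, 8),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_forward_backward_identity_and_posterior_consistency(self, seed, G, k, L):
        rng = np.random.default_rng(seed)
        m = random_model(rng, G, k)
        seq = rng.normal(0.0, 2.0, size=(L, k))
        f = hc.log_likelihood(m, seq, method="forward")
        b = hc.log_likelihood(m, seq, method="backward")
        assert f == pytest.approx(b, abs=1e-8)
        gamma, xi = hc.posteriors(m, seq)
        assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-9)
        if L > 1:
            assert np.allclose(xi.sum(axis=2), gamma[:-1], atol=1e-8)
        _, lj = hc.viterbi(m, seq)
        assert lj <= f + 1e-9

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_relabelling_states_never_changes_the_likelihood(self, seed):
        rng = np.random.default_rng(seed)
        m = random_model(rng, 3, 2)
        seq = rng.normal(size=(5, 2))
        perm = rng.permutation(3)
        assert hc.log_likelihood(m.permuted(perm), seq) == pytest.approx(
            hc.log_likelihood(m, seq), rel=1e-10
        )


def test_hmmlearn_cross_check(two_state_1d):
    """Forward log-likelihood agrees with an independent HMM library."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    _, seq = hc.sample(two_state_1d, 100, seed=42)
    ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="full", init_params="")
    ref.startprob_ = np.asarray(two_state_1d.initial)
    ref.transmat_ = np.asarray(two_state_1d.transition)
    ref.means_ = np.asarray(two_state_1d.means)
    ref.covars_ = np.asarray(two_state_1d.covariances)
    assert hc.log_likelihood(two_state_1d, seq) == pytest.approx(
        ref.score(seq), rel=1e-8
    )
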