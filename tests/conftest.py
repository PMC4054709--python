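"""Shared fixtures and independent oracles for the test suite.

The brute-force oracles here enumerate every hidden-state path explicitly
and never call the dynamic-programming recursions they are used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from vigilhmm.hmm_core import GaussianHMM


def gaussian_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    """Direct evaluation of the multivariate normal log density."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    k = len(x)
    diff = x - mean
    inv = np.linalg.inv(cov)
    _, logdet = np.linalg.slogdet(cov)
    return float(-0.5 * (k * math.log(2 * math.pi) + logdet + diff @ inv @ diff))


def enumerate_paths(hmm: GaussianHMM, seq: np.ndarray):
    """Yield (path, joint log density) over all G^L state paths."""
    seq = np.atleast_2d(seq)
    G, L = hmm.n_states, seq.shape[0]
    for path in itertools.product(range(G), repeat=L):
        lp = math.log(hmm.initial[path[0]]) if hmm.initial[path[0]] > 0 else -math.inf
        lp += gaussian_logpdf(seq[0], hmm.means[path[0]], hmm.covariances[path[0]])
        for l in range(1, L):
            a = hmm.transition[path[l - 1], path[l]]
            lp += math.log(a) if a > 0 else -math.inf
            lp += gaussian_logpdf(seq[l], hmm.means[path[l]], hmm.covariances[path[l]])
        yield path, lp


def brute_force_loglik(hmm: GaussianHMM, seq: np.ndarray) -> float:
    """log f(E | Lambda) by exhaustive path-sum enumeration."""
    tot = -math.inf
    for _, lp in enumerate_paths(hmm, seq):
        tot = np.logaddexp(tot, lp)
    return float(tot)


def brute_force_viterbi(hmm: GaussianHMM, seq: np.ndarray):
    """(best path, best joint log density) by exhaustive argmax."""
    best, best_lp = None, -math.inf
    for path, lp in enumerate_paths(hmm, seq):
        if lp > best_lp:
            best, best_lp = path, lp
    return best, best_lp


def brute_force_gamma(hmm: GaussianHMM, seq: np.ndarray) -> np.ndarray:
    """State posteriors by marginalising explicit path posteriors."""
    seq = np.atleast_2d(seq)
    G, L = hmm.n_states, seq.shape[0]
    ll = brute_force_loglik(hmm, seq)
    gamma = np.zeros((L, G))
    for path, lp in enumerate_paths(hmm, seq):
        w = math.exp(lp - ll)
        for l, j in enumerate(path):
            gamma[l, j] += w
    return gamma


def random_model(rng: np.random.Generator, G: int, k: int) -> GaussianHMM:
    """A valid random ergodic model with well-conditioned covariances."""
    A = rng.dirichlet(np.ones(G), size=G)
    pi = rng.dirichlet(np.ones(G))
    means = rng.normal(0.0, 2.0, size=(G, k))
    covs = []
    for _ in range(G):
        M = rng.normal(0.0, 1.0, size=(k, k))
        covs.append(M @ M.T + 0.5 * np.eye(k))
    return GaussianHMM(transition=A, means=means, covariances=np.array(covs), initial=pi)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def two_state_1d() -> GaussianHMM:
    """Well-separated sticky 2-state scalar model used across tests."""
    return GaussianHMM(
        transition=[[0.9, 0.1], [0.1, 0.9]],
        means=[[-3.0], [3.0]],
        covariances=np.array([np.eye(1), np.eye(1)]),
        initial=[0.5, 0.5],
    )
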