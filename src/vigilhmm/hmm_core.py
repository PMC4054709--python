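"""Continuous hidden Markov models with multivariate Gaussian emissions.

A model is Lambda = (S, X, A, B, Pi): G hidden states, continuous observation
space R^k, a G x G transition matrix A with entries a_ij = P(q_{l+1}=s_j |
q_l=s_i), per-state Gaussian emission densities b_j(x) = N(x; mu_j, Sigma_j),
and an initial-state vector Pi. The module provides the forward/backward
likelihood, posterior (gamma/xi) computation, Viterbi decoding, k-means
initialisation, Baum-Welch (EM) fitting, ancestral sampling, and JSON
serialisation.

All recursions run in log space with log-sum-exp so that sequences of
hundreds of frames do not underflow. State indices are 0-based internally;
user-facing reports elsewhere in the package convert to 1-based.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence as TSequence

import numpy as np
from scipy.linalg import solve_triangular
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


def _lse(a: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    """log-sum-exp with the max trick; tolerates -inf entries.

    Inlined rather than scipy.special.logsumexp because the recursions call
    it once per frame and the call overhead dominates at small G.
    """
    a = np.asarray(a)
    mx = a.max(axis=axis, keepdims=axis is not None)
    safe = np.where(np.isfinite(mx), mx, 0.0)
    with np.errstate(divide="ignore"):
        out = np.log(np.exp(a - safe).sum(axis=axis, keepdims=axis is not None)) + safe
    return float(out) if axis is None else np.squeeze(out, axis=axis)

_FORMAT_VERSION = "vigilhmm-hmm-1"


class InputError(ValueError):
    """Raised when caller-provided data violates a precondition."""


class ModelError(ValueError):
    """Raised when model parameters are structurally invalid."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} contains non-finite values")
    return arr


def _regularize_cov(cov: np.ndarray, floor: float) -> np.ndarray:
    """Symmetrise and add a diagonal floor; jitter further if still not PD."""
    cov = 0.5 * (cov + cov.T)
    k = cov.shape[0]
    cov = cov + floor * np.eye(k)
    # escalate the jitter until the Cholesky factorisation succeeds
    jitter = floor
    for _ in range(32):
        try:
            np.linalg.cholesky(cov)
            return cov
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-12)
            cov = cov + jitter * np.eye(k)
    raise ModelError("covariance could not be regularized to positive definite")


@dataclass
class GaussianHMM:
    """Lambda = (S, X, A, B, Pi) with Gaussian emissions.

    Attributes
    ----------
    transition : (G, G) array
        Row-stochastic state transition matrix A.
    means : (G, k) array
        Emission means mu_j, one row per state.
    covariances : (G, k, k) array
        Emission covariances Sigma_j, symmetric positive definite.
    initial : (G,) array
        Initial state probabilities Pi.
    """

    transition: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        self.transition = _as_float_array(self.transition, "transition")
        self.means = np.atleast_2d(_as_float_array(self.means, "means"))
        self.covariances = _as_float_array(self.covariances, "covariances")
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None, :, :]
        self.initial = np.atleast_1d(_as_float_array(self.initial, "initial"))
        self.validate()

    @property
    def n_states(self) -> int:
        return self.transition.shape[0]

    @property
    def obs_dim(self) -> int:
        return self.means.shape[1]

    def validate(self) -> None:
        G = self.transition.shape[0]
        k = self.means.shape[1]
        if self.transition.shape != (G, G):
            raise ModelError("transition matrix must be square")
        if self.means.shape != (G, k):
            raise ModelError("means must be G x k")
        if self.covariances.shape != (G, k, k):
            raise ModelError("covariances must be G x k x k")
        if self.initial.shape != (G,):
            raise ModelError("initial must have length G")
        if np.any(self.transition < 0) or np.any(self.initial < 0):
            raise ModelError("probabilities must be non-negative")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ModelError("transition rows must sum to 1")
        if not math.isclose(float(self.initial.sum()), 1.0, abs_tol=1e-9):
            raise ModelError("initial probabilities must sum to 1")
        for j in range(G):
            cov = self.covariances[j]
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise ModelError(f"covariance of state {j} is not symmetric")
            try:
                np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise ModelError(
                    f"covariance of state {j} is not positive definite"
                ) from exc

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GaussianHMM):
            return NotImplemented
        return (
            np.array_equal(self.transition, other.transition)
            and np.array_equal(self.means, other.means)
            and np.array_equal(self.covariances, other.covariances)
            and np.array_equal(self.initial, other.initial)
        )

    def permuted(self, perm: TSequence[int]) -> "GaussianHMM":
        """Return the model with state labels re-ordered by ``perm``.

        ``perm[i]`` is the old index that becomes new state ``i``.
        """
        p = np.asarray(perm, dtype=int)
        return GaussianHMM(
            transition=self.transition[np.ix_(p, p)],
            means=self.means[p],
            covariances=self.covariances[p],
            initial=self.initial[p],
        )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "n_states": self.n_states,
            "obs_dim": self.obs_dim,
            "transition": self.transition.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "initial": self.initial.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianHMM":
        if d.get("format_version") != _FORMAT_VERSION:
            raise InputError(f"unrecognised model format: {d.get('format_version')!r}")
        m = cls(
            transition=d["transition"],
            means=d["means"],
            covariances=d["covariances"],
            initial=d["initial"],
        )
        if m.n_states != d["n_states"] or m.obs_dim != d["obs_dim"]:
            raise InputError("model dimensions inconsistent with header")
        return m

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "GaussianHMM":
        return cls.from_dict(json.loads(s))


@dataclass
class StatePath:
    """A decoded hidden-state sequence Q = q_1 ... q_L (0-based indices)."""

    states: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)

    def __len__(self) -> int:
        return len(self.states)

    def one_based(self) -> np.ndarray:
        return self.states + 1


@dataclass
class EMTrace:
    """Per-iteration total log-likelihoods of a Baum-Welch run."""

    log_likelihoods: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


# ---------------------------------------------------------------------------
# likelihood machinery


def _check_seq(hmm: GaussianHMM, seq: np.ndarray) -> np.ndarray:
    seq = np.atleast_2d(_as_float_array(seq, "sequence"))
    if seq.shape[0] == 0:
        raise InputError("empty observation sequence")
    if seq.shape[1] != hmm.obs_dim:
        raise InputError(
            f"sequence dimension {seq.shape[1]} != model obs_dim {hmm.obs_dim}"
        )
    return seq


def emission_logdensity(hmm: GaussianHMM, x: np.ndarray) -> np.ndarray:
    """Vector of log b_j(x) for one observation x, one entry per state."""
    x = np.atleast_1d(_as_float_array(x, "observation"))
    if x.shape != (hmm.obs_dim,):
        raise InputError(f"observation has length {x.shape}, expected ({hmm.obs_dim},)")
    return _emission_logdensity_matrix(hmm, x[None, :])[0]


def _emission_logdensity_matrix(hmm: GaussianHMM, seq: np.ndarray) -> np.ndarray:
    """(L, G) matrix of log b_j(e_l), via per-state Cholesky factors."""
    L, k = seq.shape
    G = hmm.n_states
    out = np.empty((L, G))
    for j in range(G):
        try:
            chol = np.linalg.cholesky(hmm.covariances[j])
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"covariance of state {j} not positive definite") from exc
        diff = seq - hmm.means[j]
        sol = solve_triangular(chol, diff.T, lower=True)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, j] = -0.5 * (k * math.log(2.0 * math.pi) + logdet + maha)
    return out


def _log_forward(hmm: GaussianHMM, logB: np.ndarray) -> np.ndarray:
    L, G = logB.shape
    with np.errstate(divide="ignore"):
        logA = np.log(hmm.transition)
        log_pi = np.log(hmm.initial)
    alpha = np.empty((L, G))
    alpha[0] = log_pi + logB[0]
    for l in range(1, L):
        alpha[l] = _lse(alpha[l - 1][:, None] + logA, axis=0) + logB[l]
    return alpha


def _log_backward(hmm: GaussianHMM, logB: np.ndarray) -> np.ndarray:
    L, G = logB.shape
    with np.errstate(divide="ignore"):
        logA = np.log(hmm.transition)
    beta = np.empty((L, G))
    beta[L - 1] = 0.0
    for l in range(L - 2, -1, -1):
        beta[l] = _lse(logA + (logB[l + 1] + beta[l + 1])[None, :], axis=1)
    return beta


def log_likelihood(hmm: GaussianHMM, seq: np.ndarray, *, method: str = "forward") -> float:
    """log f(E | Lambda) by the forward (default) or backward recursion."""
    seq = _check_seq(hmm, seq)
    logB = _emission_logdensity_matrix(hmm, seq)
    if method == "forward":
        alpha = _log_forward(hmm, logB)
        return float(_lse(alpha[-1]))
    if method == "backward":
        beta = _log_backward(hmm, logB)
        with np.errstate(divide="ignore"):
            first = np.log(hmm.initial) + logB[0] + beta[0]
        return float(_lse(first))
    raise InputError(f"unknown method {method!r}")


def posteriors(hmm: GaussianHMM, seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """E-step quantities gamma (L x G) and xi ((L-1) x G x G).

    gamma[l, j] = P(q_l = s_j | E, Lambda); xi[l, i, j] = P(q_l = s_i,
    q_{l+1} = s_j | E, Lambda). Rows of gamma and full slices of xi each sum
    to one; marginalising xi over its second state index reproduces
    gamma[:-1].
    """
    seq = _check_seq(hmm, seq)
    logB = _emission_logdensity_matrix(hmm, seq)
    alpha = _log_forward(hmm, logB)
    beta = _log_backward(hmm, logB)
    ll = _lse(alpha[-1])
    gamma = np.exp(alpha + beta - ll)
    gamma /= gamma.sum(axis=1, keepdims=True)
    L, G = logB.shape
    with np.errstate(divide="ignore"):
        logA = np.log(hmm.transition)
    xi = np.empty((max(L - 1, 0), G, G))
    for l in range(L - 1):
        m = alpha[l][:, None] + logA + (logB[l + 1] + beta[l + 1])[None, :] - ll
        sl = np.exp(m)
        xi[l] = sl / sl.sum()
    return gamma, xi


def viterbi(hmm: GaussianHMM, seq: np.ndarray) -> tuple[StatePath, float]:
    """Most probable state path and its joint log density log f(Q*, E | Lambda).

    Ties during backtracking resolve to the lowest state index.
    """
    seq = _check_seq(hmm, seq)
    logB = _emission_logdensity_matrix(hmm, seq)
    L, G = logB.shape
    with np.errstate(divide="ignore"):
        logA = np.log(hmm.transition)
        log_pi = np.log(hmm.initial)
    delta = np.empty((L, G))
    psi = np.zeros((L, G), dtype=int)
    delta[0] = log_pi + logB[0]
    for l in range(1, L):
        cand = delta[l - 1][:, None] + logA
        psi[l] = np.argmax(cand, axis=0)  # argmax returns the first (lowest) maximiser
        delta[l] = cand[psi[l], np.arange(G)] + logB[l]
    path = np.empty(L, dtype=int)
    path[-1] = int(np.argmax(delta[-1]))
    for l in range(L - 2, -1, -1):
        path[l] = psi[l + 1, path[l + 1]]
    return StatePath(path), float(delta[-1, path[-1]])


# ---------------------------------------------------------------------------
# training


def _pool(seqs: TSequence[np.ndarray], obs_dim: int | None = None) -> list[np.ndarray]:
    if len(seqs) == 0:
        raise InputError("need at least one training sequence")
    out = []
    for s in seqs:
        s = np.atleast_2d(_as_float_array(s, "sequence"))
        if obs_dim is None:
            obs_dim = s.shape[1]
        if s.shape[1] != obs_dim:
            raise InputError("training sequences have inconsistent dimensions")
        out.append(s)
    return out


def kmeans_init(
    seqs: TSequence[np.ndarray],
    G: int,
    seed: int,
    *,
    cov_floor: float = 1e-6,
    cov_type: str = "full",
    smoothing: float = 1.0,
) -> GaussianHMM:
    """Initial model from k-means over the pooled frames.

    Centroids start uniformly at random inside the per-dimension [min, max]
    envelope of the pooled observations; after convergence mu_j is centroid j,
    Sigma_j the within-cluster covariance (floored), and A / Pi come from
    cluster-label transition and initial counts with additive smoothing.
    """
    seqs = _pool(seqs)
    X = np.vstack(seqs)
    if X.shape[0] < G:
        raise InputError(f"{X.shape[0]} pooled frames < {G} states")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    init = rng.uniform(lo, hi, size=(G, X.shape[1]))
    km = KMeans(n_clusters=G, init=init, n_init=1, random_state=int(seed) % (2**31))
    labels = km.fit_predict(X)
    means = km.cluster_centers_.copy()
    k = X.shape[1]
    covs = np.empty((G, k, k))
    pooled_cov = np.atleast_2d(np.cov(X, rowvar=False, bias=True))
    for j in range(G):
        pts = X[labels == j]
        if pts.shape[0] < 2:
            cov = pooled_cov.copy()
        else:
            cov = np.atleast_2d(np.cov(pts, rowvar=False, bias=True))
        if cov_type == "diag":
            cov = np.diag(np.diag(cov))
        covs[j] = _regularize_cov(cov, cov_floor)
    # transition / initial counts from the label streams, per sequence
    trans = np.full((G, G), smoothing)
    init_counts = np.full(G, smoothing)
    pos = 0
    for s in seqs:
        lab = labels[pos : pos + s.shape[0]]
        pos += s.shape[0]
        init_counts[lab[0]] += 1
        np.add.at(trans, (lab[:-1], lab[1:]), 1)
    A = trans / trans.sum(axis=1, keepdims=True)
    pi = init_counts / init_counts.sum()
    return GaussianHMM(transition=A, means=means, covariances=covs, initial=pi)


def fit_em(
    seqs: TSequence[np.ndarray],
    G: int,
    *,
    max_iter: int = 100,
    tol: float = 1e-4,
    seed: int = 0,
    cov_floor: float = 1e-6,
    cov_type: str = "full",
    init: GaussianHMM | None = None,
) -> tuple[GaussianHMM, EMTrace]:
    """Baum-Welch fit starting from ``kmeans_init`` (or a supplied model).

    E-step statistics are summed across all sequences before each M-step.
    Stops when the total log-likelihood gain drops below ``tol`` or after
    ``max_iter`` iterations. States that lose all posterior mass keep their
    previous parameters (with a floored covariance) and a warning is logged.
    """
    seqs = _pool(seqs)
    hmm = init if init is not None else kmeans_init(
        seqs, G, seed, cov_floor=cov_floor, cov_type=cov_type
    )
    if init is not None and hmm.n_states != G:
        raise InputError("supplied init model has wrong number of states")
    trace = EMTrace()
    k = hmm.obs_dim
    total_frames = sum(s.shape[0] for s in seqs)
    for it in range(max_iter):
        pi_acc = np.zeros(G)
        trans_acc = np.zeros((G, G))
        w_acc = np.zeros(G)
        mean_acc = np.zeros((G, k))
        sq_acc = np.zeros((G, k, k))
        total_ll = 0.0
        for s in seqs:
            logB = _emission_logdensity_matrix(hmm, s)
            alpha = _log_forward(hmm, logB)
            beta = _log_backward(hmm, logB)
            ll = float(_lse(alpha[-1]))
            total_ll += ll
            gamma = np.exp(alpha + beta - ll)
            gamma /= gamma.sum(axis=1, keepdims=True)
            pi_acc += gamma[0]
            if s.shape[0] > 1:
                with np.errstate(divide="ignore"):
                    logA = np.log(hmm.transition)
                for l in range(s.shape[0] - 1):
                    m = alpha[l][:, None] + logA + (logB[l + 1] + beta[l + 1])[None, :] - ll
                    trans_acc += np.exp(m)
            w_acc += gamma.sum(axis=0)
            mean_acc += gamma.T @ s
            for j in range(G):
                sq_acc[j] += (gamma[:, j][:, None] * s).T @ s
        trace.log_likelihoods.append(total_ll)
        trace.n_iter = it + 1
        if it > 0 and total_ll - trace.log_likelihoods[-2] < tol:
            trace.converged = True
            break
        # M-step
        new_A = hmm.transition.copy()
        row = trans_acc.sum(axis=1)
        ok = row > 1e-300
        new_A[ok] = trans_acc[ok] / row[ok, None]
        new_pi = pi_acc / pi_acc.sum()
        new_means = hmm.means.copy()
        new_covs = hmm.covariances.copy()
        for j in range(G):
            if w_acc[j] < 1e-10 * total_frames:
                logger.warning(
                    "state %d lost posterior mass during EM; keeping previous "
                    "parameters with floored covariance",
                    j,
                )
                new_covs[j] = _regularize_cov(hmm.covariances[j], cov_floor)
                continue
            mu = mean_acc[j] / w_acc[j]
            cov = sq_acc[j] / w_acc[j] - np.outer(mu, mu)
            if cov_type == "diag":
                cov = np.diag(np.diag(cov))
            new_means[j] = mu
            new_covs[j] = _regularize_cov(cov, cov_floor)
        hmm = GaussianHMM(
            transition=new_A, means=new_means, covariances=new_covs, initial=new_pi
        )
    return hmm, trace


def total_log_likelihood(hmm: GaussianHMM, seqs: TSequence[np.ndarray]) -> float:
    """Sum of per-sequence log-likelihoods (convenience for diagnostics)."""
    return float(sum(log_likelihood(hmm, s) for s in _pool(seqs, hmm.obs_dim)))


# ---------------------------------------------------------------------------
# sampling


def sample(hmm: GaussianHMM, L: int, seed: int) -> tuple[StatePath, np.ndarray]:
    """Draw a state path from (Pi, A) and observations from the state Gaussians."""
    if L < 1:
        raise InputError("sequence length must be >= 1")
    rng = np.random.default_rng(seed)
    G, k = hmm.n_states, hmm.obs_dim
    chols = np.array([np.linalg.cholesky(hmm.covariances[j]) for j in range(G)])
    path = np.empty(L, dtype=int)
    path[0] = rng.choice(G, p=hmm.initial)
    for l in range(1, L):
        path[l] = rng.choice(G, p=hmm.transition[path[l - 1]])
    noise = rng.standard_normal((L, k))
    seq = hmm.means[path] + np.einsum("lij,lj->li", chols[path], noise)
    return StatePath(path), seq


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary vector of an ergodic transition matrix (left eigenvector)."""
    A = np.asarray(transition, dtype=float)
    vals, vecs = np.linalg.eig(A.T)
    idx = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, idx])
    v = np.abs(v)
    return v / v.sum()
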