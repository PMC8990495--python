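"""Gaussian-emission hidden Markov models of fixation sequences.

Each participant-condition's scanpaths are summarized by an HMM whose hidden
states are person-specific regions of interest (ROIs) with 2-D Gaussian
emissions over fixation position, a prior distribution over the starting ROI,
and a row-stochastic ROI transition matrix.  Fixation durations are carried in
the data model but not modelled: emissions are positions only.

Fitting uses variational Bayesian EM (VBEM) with conjugate priors — Dirichlet
on the prior vector and on each transition row, Normal–Wishart on each ROI's
mean and precision.  The variational lower bound both drives convergence and
scores candidate models, so the number of ROIs can be selected by refitting
over a preset range (1–10 by default) and keeping the highest bound.

The module also provides exact forward log-likelihood, Viterbi decoding of the
most probable ROI sequence, ancestral sampling, and JSON (de)serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import digamma, gammaln, logsumexp
from sklearn.cluster import KMeans

from .data import FixationSequence, MASK_NA, PHASE_RECOGNITION
from .exceptions import InputError, ModelDegeneracyError

_DIM = 2  # fixations are (x, y)
MAX_ROIS = 10

# Default face box (width, height) in pixels, centered between the eyes.
# Used only to scale weakly-informative priors.
DEFAULT_FACE_BOX = (320.0, 400.0)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class GaussianHMM:
    """An HMM with 2-D Gaussian ROI emissions.

    Attributes
    ----------
    prior : (K,) probability vector over the starting ROI.
    transitions : (K, K) row-stochastic ROI transition matrix.
    means : (K, 2) ROI centers in face-centered pixels.
    covariances : (K, 2, 2) symmetric positive-definite ROI covariances.
    """

    prior: np.ndarray
    transitions: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self) -> None:
        self.prior = np.asarray(self.prior, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)

    @property
    def n_rois(self) -> int:
        return self.prior.shape[0]

    def validate(self, atol: float = 1e-8) -> None:
        """Raise :class:`InputError` on any violated structural invariant."""
        K = self.n_rois
        if not 1 <= K <= MAX_ROIS:
            raise InputError(f"number of ROIs must be in [1, {MAX_ROIS}], got {K}")
        if self.transitions.shape != (K, K):
            raise InputError("transition matrix shape mismatch")
        if self.means.shape != (K, _DIM) or self.covariances.shape != (K, _DIM, _DIM):
            raise InputError("emission parameter shape mismatch")
        if np.any(self.prior < 0) or abs(self.prior.sum() - 1.0) > atol:
            raise InputError("prior must be a probability vector")
        if np.any(self.transitions < 0) or np.any(
            np.abs(self.transitions.sum(axis=1) - 1.0) > atol
        ):
            raise InputError("transition rows must be probability vectors")
        for k in range(K):
            c = self.covariances[k]
            if not np.allclose(c, c.T, atol=1e-10):
                raise InputError(f"covariance {k} is not symmetric")
            if np.linalg.eigvalsh(c)[0] <= 0:
                raise ModelDegeneracyError(f"covariance {k} is not positive-definite")

    def permuted(self, perm: Sequence[int]) -> "GaussianHMM":
        """Relabel hidden states by ``perm`` (new index i takes old state perm[i])."""
        p = np.asarray(perm)
        return GaussianHMM(
            prior=self.prior[p],
            transitions=self.transitions[np.ix_(p, p)],
            means=self.means[p],
            covariances=self.covariances[p],
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_rois": self.n_rois,
            "prior": self.prior.tolist(),
            "transitions": self.transitions.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianHMM":
        m = cls(
            prior=np.array(d["prior"], dtype=float),
            transitions=np.array(d["transitions"], dtype=float),
            means=np.array(d["means"], dtype=float),
            covariances=np.array(d["covariances"], dtype=float),
        )
        if "n_rois" in d and int(d["n_rois"]) != m.n_rois:
            raise InputError("stored n_rois is inconsistent with parameters")
        return m

    def save(self, path, provenance: dict | None = None) -> None:
        payload = self.to_dict()
        if provenance:
            payload["provenance"] = provenance
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "GaussianHMM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class VBHyper:
    """Hyperparameters of the conjugate VBEM priors.

    The defaults are weakly informative: ROI means are centered on the face
    with negligible strength, the covariance prior is scaled to a quarter of
    the face box per axis, and all Dirichlet concentrations are 1 (uniform).
    """

    mean_prior_center: tuple[float, float] = (0.0, 0.0)
    mean_prior_strength: float = 0.01
    covariance_prior_scale: np.ndarray = field(
        default_factory=lambda: np.diag(
            [(DEFAULT_FACE_BOX[0] / 4.0) ** 2, (DEFAULT_FACE_BOX[1] / 4.0) ** 2]
        )
    )
    covariance_prior_dof: float = 5.0
    dirichlet_concentration_prior: float = 1.0

    def validate(self) -> None:
        if self.mean_prior_strength <= 0:
            raise InputError("mean_prior_strength must be positive")
        if self.dirichlet_concentration_prior <= 0:
            raise InputError("dirichlet_concentration_prior must be positive")
        if self.covariance_prior_dof <= _DIM - 1:
            raise InputError("covariance_prior_dof must exceed dim - 1")
        s = np.asarray(self.covariance_prior_scale, dtype=float)
        if s.shape != (_DIM, _DIM) or np.linalg.eigvalsh(s)[0] <= 0:
            raise InputError("covariance_prior_scale must be 2x2 positive-definite")


@dataclass
class FitResult:
    """Outcome of one VBEM fit (possibly best-of-restarts / best-of-K)."""

    model: GaussianHMM
    lower_bound: float
    n_rois_selected: int
    n_restarts_used: int
    converged: bool
    seed: int


# ---------------------------------------------------------------------------
# Exact inference on a fitted model
# ---------------------------------------------------------------------------

def _emission_logpdf(model: GaussianHMM, X: np.ndarray) -> np.ndarray:
    """Per-state Gaussian log density, shape (T, K)."""
    T = X.shape[0]
    K = model.n_rois
    out = np.empty((T, K))
    for k in range(K):
        try:
            chol = cho_factor(model.covariances[k], lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises ValueError
            raise ModelDegeneracyError(f"singular covariance for ROI {k}") from exc
        logdet = 2.0 * np.sum(np.log(np.diag(chol[0])))
        diff = X - model.means[k]
        maha = np.sum(diff * cho_solve(chol, diff.T).T, axis=1)
        out[:, k] = -0.5 * (_DIM * np.log(2 * np.pi) + logdet + maha)
    return out


def _check_model_seq(model: GaussianHMM, seq) -> np.ndarray:
    model.validate()
    X = seq.positions if isinstance(seq, FixationSequence) else np.asarray(seq, float)
    if X.ndim != 2 or X.shape[1] != _DIM or X.shape[0] == 0:
        raise InputError("sequence must contain at least one (x, y) fixation")
    return X


def log_likelihood(model: GaussianHMM, seq) -> float:
    """Forward log-likelihood log p(x_1..x_T | model), in nats.

    Computed by the forward recursion in log space over fixation positions;
    durations are ignored.  ``seq`` may be a :class:`FixationSequence` or a
    bare (T, 2) position array.
    """
    X = _check_model_seq(model, seq)
    logB = _emission_logpdf(model, X)
    log_alpha = np.log(np.clip(model.prior, 1e-300, None)) + logB[0]
    logA = np.log(np.clip(model.transitions, 1e-300, None))
    for t in range(1, X.shape[0]):
        log_alpha = logsumexp(log_alpha[:, None] + logA, axis=0) + logB[t]
    return float(logsumexp(log_alpha))


def log_likelihoods(model: GaussianHMM, seqs: Iterable) -> np.ndarray:
    """Forward log-likelihood of every sequence, batched by length."""
    model.validate()
    Xs = [s.positions if isinstance(s, FixationSequence) else np.asarray(s, float)
          for s in seqs]
    if not Xs:
        raise InputError("need at least one sequence")
    out = np.empty(len(Xs))
    for T, idxs in _group_by_length(Xs).items():
        if T == 0:
            raise InputError("sequence must contain at least one (x, y) fixation")
        batch = np.stack([Xs[i] for i in idxs])
        logB = _emission_logpdf(model, batch.reshape(-1, _DIM)) \
            .reshape(len(idxs), T, model.n_rois)
        _, _, ll = _forward_backward_batch(logB, model.prior, model.transitions)
        out[idxs] = ll
    return out


def mean_log_likelihood(model: GaussianHMM, seqs: Iterable) -> float:
    """Mean per-sequence forward log-likelihood over ``seqs``."""
    return float(np.mean(log_likelihoods(model, list(seqs))))


def decode_rois(model: GaussianHMM, seq) -> np.ndarray:
    """Most probable joint ROI sequence (Viterbi path).

    Ties are broken deterministically toward the lower ROI index.
    """
    X = _check_model_seq(model, seq)
    logB = _emission_logpdf(model, X)
    logA = np.log(np.clip(model.transitions, 1e-300, None))
    T, K = logB.shape
    delta = np.log(np.clip(model.prior, 1e-300, None)) + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def sample_sequences(
    model: GaussianHMM,
    n_trials: int,
    length_dist: int | Callable[[np.random.Generator], int],
    seed: int,
    *,
    participant_id: str = "sim",
    phase: str = PHASE_RECOGNITION,
    learn_mask: str = "unmasked",
    recog_mask: str | None = "unmasked",
) -> list[FixationSequence]:
    """Draw fixation sequences from the model by ancestral sampling.

    ``length_dist`` is either a fixed positive integer or a callable taking a
    :class:`numpy.random.Generator` and returning a positive integer length.
    Durations are sampled from a gamma distribution (mean ~250 ms) purely to
    populate the data model; the HMM itself never uses them.
    """
    model.validate()
    if n_trials < 1:
        raise InputError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    chols = np.linalg.cholesky(model.covariances)
    if recog_mask is None:
        recog_mask = MASK_NA
    out = []
    for trial in range(n_trials):
        T = length_dist if isinstance(length_dist, (int, np.integer)) else int(length_dist(rng))
        if T < 1:
            raise InputError("length distribution produced a non-positive length")
        states = np.empty(T, dtype=int)
        states[0] = rng.choice(model.n_rois, p=model.prior)
        for t in range(1, T):
            states[t] = rng.choice(model.n_rois, p=model.transitions[states[t - 1]])
        noise = rng.standard_normal((T, _DIM))
        pos = model.means[states] + np.einsum("tij,tj->ti", chols[states], noise)
        durs = rng.gamma(shape=4.0, scale=62.5, size=T)
        durs = np.maximum(durs, 1.0)
        out.append(
            FixationSequence(
                participant_id=participant_id,
                trial_id=f"{participant_id}_t{trial}",
                phase=phase,
                learn_mask=learn_mask,
                recog_mask=recog_mask,
                fixations=np.column_stack([pos, durs]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Batched forward-backward (shared with the HMM-clustering module)
# ---------------------------------------------------------------------------

def _forward_backward_batch(
    logB: np.ndarray, pi: np.ndarray, A: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward-backward over a batch of equal-length sequences.

    Parameters are plain (possibly unnormalized) weights ``pi`` (K,) and
    ``A`` (K, K); ``logB`` has shape (B, T, K).  Returns
    ``(gamma, xi_sum, loglik)`` with shapes (B, T, K), (B, K, K), (B,).
    The log-likelihoods are exact up to the normalization of pi/A, which is
    what the variational E-step requires.
    """
    B, T, K = logB.shape
    shift = logB.max(axis=2)
    Btil = np.exp(logB - shift[:, :, None])  # (B, T, K), entries in (0, 1]

    alpha = np.empty((B, T, K))
    c = np.empty((B, T))
    a = pi[None, :] * Btil[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0:1]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * Btil[:, t]
        c[:, t] = a.sum(axis=1)
        alpha[:, t] = a / c[:, t:t + 1]

    beta = np.empty((B, T, K))
    beta[:, T - 1] = 1.0
    xi_sum = np.zeros((B, K, K))
    for t in range(T - 1, 0, -1):
        bb = Btil[:, t] * beta[:, t]  # (B, K)
        xi_sum += alpha[:, t - 1, :, None] * A[None, :, :] * bb[:, None, :] / c[:, t, None, None]
        beta[:, t - 1] = (bb @ A.T) / c[:, t:t + 1]

    gamma = alpha * beta
    loglik = np.log(c).sum(axis=1) + shift.sum(axis=1)
    return gamma, xi_sum, loglik


def _group_by_length(Xs: list[np.ndarray]) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for i, x in enumerate(Xs):
        groups.setdefault(x.shape[0], []).append(i)
    return groups


# ---------------------------------------------------------------------------
# VBEM
# ---------------------------------------------------------------------------

class _VBPosterior:
    """Variational posterior: Dirichlet over pi and transition rows,
    Normal-Wishart over each ROI's (mean, precision)."""

    __slots__ = ("alpha_pi", "alpha_A", "beta", "m", "W", "nu")

    def __init__(self, alpha_pi, alpha_A, beta, m, W, nu):
        self.alpha_pi = alpha_pi
        self.alpha_A = alpha_A
        self.beta = beta
        self.m = m
        self.W = W
        self.nu = nu

    @property
    def n_states(self) -> int:
        return self.alpha_pi.shape[0]


def _expected_log_pi_A(post: _VBPosterior) -> tuple[np.ndarray, np.ndarray]:
    log_pi = digamma(post.alpha_pi) - digamma(post.alpha_pi.sum())
    log_A = digamma(post.alpha_A) - digamma(post.alpha_A.sum(axis=1, keepdims=True))
    return log_pi, log_A


def _expected_logdet_precision(post: _VBPosterior) -> np.ndarray:
    K = post.n_states
    out = np.empty(K)
    for k in range(K):
        _, logdet = np.linalg.slogdet(post.W[k])
        out[k] = (
            digamma(0.5 * (post.nu[k] - np.arange(_DIM)))
        ).sum() + _DIM * np.log(2.0) + logdet
    return out


def _expected_emission_logpdf(post: _VBPosterior, X: np.ndarray) -> np.ndarray:
    """E_q[log N(x | mu_k, Lambda_k^-1)], shape (T, K)."""
    K = post.n_states
    T = X.shape[0]
    elogdet = _expected_logdet_precision(post)
    out = np.empty((T, K))
    for k in range(K):
        diff = X - post.m[k]
        maha = post.nu[k] * np.einsum("ti,ij,tj->t", diff, post.W[k], diff)
        out[:, k] = 0.5 * (
            elogdet[k] - _DIM * np.log(2 * np.pi) - _DIM / post.beta[k] - maha
        )
    return out


def _kl_dirichlet(a: np.ndarray, a0: np.ndarray) -> float:
    sa, sa0 = a.sum(), a0.sum()
    return float(
        gammaln(sa)
        - gammaln(sa0)
        - (gammaln(a) - gammaln(a0)).sum()
        + ((a - a0) * (digamma(a) - digamma(sa))).sum()
    )


def _log_wishart_B(W: np.ndarray, nu: float) -> float:
    _, logdet = np.linalg.slogdet(W)
    return float(
        -0.5 * nu * logdet
        - 0.5 * nu * _DIM * np.log(2.0)
        - 0.25 * _DIM * (_DIM - 1) * np.log(np.pi)
        - gammaln(0.5 * (nu - np.arange(_DIM))).sum()
    )


def _kl_normal_wishart(post: _VBPosterior, k: int, hyper: "_HyperArrays") -> float:
    beta, m, W, nu = post.beta[k], post.m[k], post.W[k], post.nu[k]
    beta0, m0, W0inv, nu0, W0 = hyper.beta0, hyper.m0, hyper.W0inv, hyper.nu0, hyper.W0
    elogdet = (
        digamma(0.5 * (nu - np.arange(_DIM)))
    ).sum() + _DIM * np.log(2.0) + np.linalg.slogdet(W)[1]
    # KL of the conditional Gaussian over the mean
    diff = m - m0
    kl_mu = 0.5 * (
        _DIM * np.log(beta / beta0)
        + _DIM * (beta0 / beta - 1.0)
        + beta0 * nu * diff @ W @ diff
    )
    # KL of the Wishart over the precision
    kl_lam = (
        _log_wishart_B(W, nu)
        - _log_wishart_B(W0, nu0)
        + 0.5 * (nu - nu0) * elogdet
        + 0.5 * nu * (np.trace(W0inv @ W) - _DIM)
    )
    return float(kl_mu + kl_lam)


class _HyperArrays:
    """Prior hyperparameters broadcast to arrays for a K-state fit."""

    def __init__(self, hyper: VBHyper, K: int):
        hyper.validate()
        self.alpha0 = float(hyper.dirichlet_concentration_prior)
        self.beta0 = float(hyper.mean_prior_strength)
        self.m0 = np.asarray(hyper.mean_prior_center, dtype=float)
        self.nu0 = float(hyper.covariance_prior_dof)
        scale = np.asarray(hyper.covariance_prior_scale, dtype=float)
        # Prior scale chosen so the prior mean of the ROI covariance equals
        # covariance_prior_scale: E[Sigma] = W0^-1 / (nu0 - d - 1).
        excess = max(self.nu0 - _DIM - 1.0, 1.0)
        self.W0inv = scale * excess
        self.W0 = np.linalg.inv(self.W0inv)
        self.K = K


def _m_step(
    stats_pi: np.ndarray,
    stats_A: np.ndarray,
    Nk: np.ndarray,
    xbar: np.ndarray,
    Sk: np.ndarray,
    hyper: _HyperArrays,
) -> _VBPosterior:
    K = hyper.K
    alpha_pi = hyper.alpha0 + stats_pi
    alpha_A = hyper.alpha0 + stats_A
    beta = hyper.beta0 + Nk
    nu = hyper.nu0 + Nk
    m = (hyper.beta0 * hyper.m0[None, :] + Nk[:, None] * xbar) / beta[:, None]
    W = np.empty((K, _DIM, _DIM))
    for k in range(K):
        diff = (xbar[k] - hyper.m0)[:, None]
        Winv = (
            hyper.W0inv
            + Nk[k] * Sk[k]
            + (hyper.beta0 * Nk[k] / beta[k]) * (diff @ diff.T)
        )
        W[k] = np.linalg.inv(Winv)
    return _VBPosterior(alpha_pi, alpha_A, beta, m, W, nu)


def _e_step(
    Xs: list[np.ndarray],
    groups: dict[int, list[int]],
    post: _VBPosterior,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, float]:
    """Accumulate expected sufficient statistics; return them plus the
    expected-parameter log-likelihood term of the lower bound."""
    K = post.n_states
    log_pi, log_A = _expected_log_pi_A(post)
    pi_t, A_t = np.exp(log_pi), np.exp(log_A)
    stats_pi = np.zeros(K)
    stats_A = np.zeros((K, K))
    Nk = np.zeros(K)
    sum_x = np.zeros((K, _DIM))
    sum_xx = np.zeros((K, _DIM, _DIM))
    total_ll = 0.0
    for T, idxs in groups.items():
        Xb = np.stack([Xs[i] for i in idxs])  # (B, T, 2)
        logB = np.stack([_expected_emission_logpdf(post, x) for x in Xb])
        gamma, xi_sum, ll = _forward_backward_batch(logB, pi_t, A_t)
        total_ll += ll.sum()
        stats_pi += gamma[:, 0, :].sum(axis=0)
        stats_A += xi_sum.sum(axis=0)
        g = gamma.reshape(-1, K)  # (B*T, K)
        flat = Xb.reshape(-1, _DIM)
        Nk += g.sum(axis=0)
        sum_x += g.T @ flat
        sum_xx += np.einsum("tk,ti,tj->kij", g, flat, flat)
    Nk_safe = np.maximum(Nk, 1e-12)
    xbar = sum_x / Nk_safe[:, None]
    Sk = sum_xx / Nk_safe[:, None, None] - np.einsum("ki,kj->kij", xbar, xbar)
    # guard against tiny negative eigenvalues from cancellation
    Sk += 1e-10 * np.eye(_DIM)[None, :, :]
    return stats_pi, stats_A, Nk, xbar, Sk, total_ll


def _elbo(post: _VBPosterior, hyper: _HyperArrays, expected_ll: float) -> float:
    K = post.n_states
    kl = _kl_dirichlet(post.alpha_pi, np.full(K, hyper.alpha0))
    for i in range(K):
        kl += _kl_dirichlet(post.alpha_A[i], np.full(K, hyper.alpha0))
    for k in range(K):
        kl += _kl_normal_wishart(post, k, hyper)
    return expected_ll - kl


def _init_posterior(
    Xs: list[np.ndarray], K: int, hyper: _HyperArrays, seed: int
) -> _VBPosterior:
    """Initialize from a k-means hard labelling of the pooled fixations."""
    pooled = np.concatenate(Xs, axis=0)
    if K == 1:
        labels = np.zeros(pooled.shape[0], dtype=int)
    else:
        km = KMeans(n_clusters=K, n_init=1, random_state=int(seed) % (2**31))
        labels = km.fit_predict(pooled)
    onehot = np.eye(K)[labels]
    Nk = onehot.sum(axis=0)
    Nk_safe = np.maximum(Nk, 1e-12)
    xbar = (onehot.T @ pooled) / Nk_safe[:, None]
    Sk = np.zeros((K, _DIM, _DIM))
    for k in range(K):
        diff = pooled[labels == k] - xbar[k]
        if diff.shape[0]:
            Sk[k] = diff.T @ diff / diff.shape[0]
        Sk[k] += 1e-8 * np.eye(_DIM)
    # initial-state / bigram counts from the hard labels
    stats_pi = np.zeros(K)
    stats_A = np.zeros((K, K))
    ofs = 0
    for x in Xs:
        lab = labels[ofs:ofs + x.shape[0]]
        stats_pi[lab[0]] += 1
        np.add.at(stats_A, (lab[:-1], lab[1:]), 1)
        ofs += x.shape[0]
    return _m_step(stats_pi, stats_A, Nk, xbar, Sk, hyper)


def _point_estimate(
    post: _VBPosterior, hyper: _HyperArrays, Nk: np.ndarray, prune_threshold: float
) -> GaussianHMM:
    keep = np.where(Nk >= prune_threshold)[0]
    if keep.size == 0:
        keep = np.array([int(np.argmax(Nk))])
    alpha_pi = post.alpha_pi[keep]
    alpha_A = post.alpha_A[np.ix_(keep, keep)]
    pi = alpha_pi / alpha_pi.sum()
    A = alpha_A / alpha_A.sum(axis=1, keepdims=True)
    covs = np.empty((keep.size, _DIM, _DIM))
    for j, k in enumerate(keep):
        denom = post.nu[k] - _DIM - 1.0
        covs[j] = np.linalg.inv(post.W[k]) / max(denom, 1.0)
    return GaussianHMM(prior=pi, transitions=A, means=post.m[keep].copy(), covariances=covs)


def _vbem_single(
    Xs: list[np.ndarray],
    K: int,
    hyper: _HyperArrays,
    seed: int,
    max_iter: int,
    tol: float,
) -> tuple[_VBPosterior, np.ndarray, float, bool]:
    groups = _group_by_length(Xs)
    post = _init_posterior(Xs, K, hyper, seed)
    prev = -np.inf
    converged = False
    Nk = np.zeros(K)
    for _ in range(max_iter):
        stats_pi, stats_A, Nk, xbar, Sk, expected_ll = _e_step(Xs, groups, post)
        bound = _elbo(post, hyper, expected_ll)
        if bound - prev < tol and np.isfinite(prev):
            converged = True
            prev = max(prev, bound)
            break
        prev = bound
        post = _m_step(stats_pi, stats_A, Nk, xbar, Sk, hyper)
    return post, Nk, prev, converged


def fit_vbem(
    seqs: Sequence,
    n_rois: int,
    hyper: VBHyper | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    *,
    max_iter: int = 300,
    tol: float = 1e-6,
    prune_threshold: float = 1e-3,
) -> FitResult:
    """Fit a K-ROI Gaussian HMM to fixation sequences by VBEM.

    Runs ``n_restarts`` seeded restarts (k-means initialization of the ROI
    responsibilities) and returns the restart with the highest variational
    lower bound.  ROIs whose expected occupancy over the training data falls
    below ``prune_threshold`` fixations are pruned from the returned model, so
    the effective number of ROIs may be smaller than requested.

    Identical inputs and seed reproduce the result bit-for-bit.
    """
    if n_restarts < 1:
        raise InputError("n_restarts must be >= 1")
    if not seqs:
        raise InputError("need at least one sequence")
    Xs = [
        s.positions if isinstance(s, FixationSequence) else np.asarray(s, float)
        for s in seqs
    ]
    total = sum(x.shape[0] for x in Xs)
    if n_rois < 1 or n_rois > total:
        raise InputError(
            f"n_rois must be in [1, total fixation count={total}], got {n_rois}"
        )
    hy = _HyperArrays(hyper or VBHyper(), n_rois)
    rng = np.random.default_rng(seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=n_restarts)
    best = None
    for rs in restart_seeds:
        post, Nk, bound, conv = _vbem_single(Xs, n_rois, hy, int(rs), max_iter, tol)
        if best is None or bound > best[2]:
            best = (post, Nk, bound, conv)
    post, Nk, bound, conv = best
    model = _point_estimate(post, hy, Nk, prune_threshold)
    return FitResult(
        model=model,
        lower_bound=float(bound),
        n_rois_selected=model.n_rois,
        n_restarts_used=n_restarts,
        converged=bool(conv),
        seed=seed,
    )


def select_n_rois(
    seqs: Sequence,
    roi_range: Iterable[int] = range(1, MAX_ROIS + 1),
    hyper: VBHyper | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    **fit_kwargs,
) -> FitResult:
    """Fit each candidate number of ROIs and keep the best lower bound.

    Candidates are fitted independently; ties within 1e-8 of the best bound
    are broken toward the smaller K.  The returned ``n_rois_selected`` refers
    to the post-pruning model.
    """
    ks = sorted(set(int(k) for k in roi_range))
    if not ks:
        raise InputError("roi_range must be non-empty")
    if ks[0] < 1 or ks[-1] > MAX_ROIS:
        raise InputError(f"roi_range must lie within [1, {MAX_ROIS}]")
    best: FitResult | None = None
    for k in ks:
        res = fit_vbem(seqs, k, hyper, n_restarts, seed, **fit_kwargs)
        if best is None or res.lower_bound > best.lower_bound + 1e-8:
            best = res
    return best
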