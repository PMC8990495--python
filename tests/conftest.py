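"""Shared fixtures and independent oracles for the test suite."""

from itertools import product

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from gazehmm.hmm import GaussianHMM


# ---------------------------------------------------------------------------
# brute-force oracles (path enumeration; independent of the forward/Viterbi
# implementations under test)
# ---------------------------------------------------------------------------

def brute_force_loglik(model: GaussianHMM, X: np.ndarray) -> float:
    """log p(X) by summation over every hidden-state path."""
    K, T = model.n_rois, X.shape[0]
    total = -np.inf
    for path in product(range(K), repeat=T):
        lp = np.log(model.prior[path[0]])
        for t in range(1, T):
            lp += np.log(model.transitions[path[t - 1], path[t]])
        for t in range(T):
            lp += multivariate_normal.logpdf(
                X[t], model.means[path[t]], model.covariances[path[t]])
        total = np.logaddexp(total, lp)
    return float(total)


def brute_force_viterbi(model: GaussianHMM, X: np.ndarray) -> tuple:
    """Arg-max over every hidden-state path; ties toward the lexicographically
    smallest path, matching the documented lower-index tie rule."""
    K, T = model.n_rois, X.shape[0]
    best, best_lp = None, -np.inf
    for path in product(range(K), repeat=T):
        lp = np.log(model.prior[path[0]])
        for t in range(1, T):
            lp += np.log(model.transitions[path[t - 1], path[t]])
        for t in range(T):
            lp += multivariate_normal.logpdf(
                X[t], model.means[path[t]], model.covariances[path[t]])
        if lp > best_lp + 1e-12:
            best, best_lp = path, lp
    return best


def random_model(rng: np.random.Generator, K: int) -> GaussianHMM:
    """A random valid K-state model with well-conditioned covariances."""
    prior = rng.dirichlet(np.ones(K) * 2)
    trans = np.stack([rng.dirichlet(np.ones(K) * 2) for _ in range(K)])
    means = rng.uniform(-100, 100, size=(K, 2))
    covs = []
    for _ in range(K):
        a = rng.normal(0, 1, (2, 2))
        covs.append(a @ a.T + np.eye(2) * rng.uniform(50, 200))
    return GaussianHMM(prior, trans, means, np.stack(covs))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def printed_two_state():
    """The 2-state model whose entropies were hand-summed in advance."""
    return GaussianHMM(
        prior=np.array([0.7, 0.3]),
        transitions=np.array([[0.8, 0.2], [0.4, 0.6]]),
        means=np.array([[-10.0, 0.0], [10.0, 0.0]]),
        covariances=np.stack([np.eye(2) * 25.0] * 2),
    )


@pytest.fixture(scope="session")
def separated_three_roi():
    """Well-separated 3-ROI generator used by the recovery simulations.

    ROI centers are >= 6 posterior standard deviations apart given the
    10-pixel emission scale.
    """
    return GaussianHMM(
        prior=np.array([0.5, 0.3, 0.2]),
        transitions=np.array([
            [0.6, 0.3, 0.1],
            [0.2, 0.7, 0.1],
            [0.15, 0.15, 0.7],
        ]),
        means=np.array([[-80.0, 0.0], [80.0, 0.0], [0.0, 100.0]]),
        covariances=np.stack([np.diag([100.0, 100.0])] * 3),
    )


@pytest.fixture(scope="session")
def printed_k2():
    """Small K=2 model with fixed printed parameters for oracle checks."""
    return GaussianHMM(
        prior=np.array([0.6, 0.4]),
        transitions=np.array([[0.7, 0.3], [0.2, 0.8]]),
        means=np.array([[-20.0, 5.0], [25.0, -10.0]]),
        covariances=np.stack([np.diag([30.0, 40.0]), np.diag([50.0, 20.0])]),
    )
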