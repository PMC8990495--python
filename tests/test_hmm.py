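"""Unit and property tests of the HMM core: exact inference, VBEM fitting,
model selection, decoding, and sampling."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from gazehmm.data import FixationSequence
from gazehmm.exceptions import InputError, ModelDegeneracyError
from gazehmm.hmm import (
    GaussianHMM,
    VBHyper,
    decode_rois,
    fit_vbem,
    log_likelihood,
    sample_sequences,
    select_n_rois,
)

from conftest import brute_force_loglik, brute_force_viterbi, random_model


def _seq(X):
    X = np.asarray(X, float)
    fx = np.column_stack([X, np.full(len(X), 200.0)])
    return FixationSequence("p0", "t0", "recognition", "unmasked", "unmasked", fx)


# ---------------------------------------------------------------------------
# forward log-likelihood
# ---------------------------------------------------------------------------

class TestLogLikelihood:
    def test_k1_closed_form(self):
        model = GaussianHMM(np.array([1.0]), np.array([[1.0]]),
                            np.array([[3.0, -2.0]]),
                            np.array([[[40.0, 5.0], [5.0, 30.0]]]))
        X = np.array([[0.0, 0.0], [5.0, -4.0], [2.0, 1.0]])
        expected = multivariate_normal.logpdf(
            X, model.means[0], model.covariances[0]).sum()
        assert log_likelihood(model, X) == pytest.approx(expected, abs=1e-10)

    def test_length_one_is_log_mixture(self, printed_k2):
        x = np.array([[4.0, 2.0]])
        dens = sum(
            printed_k2.prior[k] * multivariate_normal.pdf(
                x[0], printed_k2.means[k], printed_k2.covariances[k])
            for k in range(2))
        assert log_likelihood(printed_k2, x) == pytest.approx(np.log(dens), abs=1e-10)

    def test_matches_path_enumeration_k2_t3(self, printed_k2):
        X = np.array([[-18.0, 6.0], [20.0, -8.0], [0.0, 0.0]])
        assert log_likelihood(printed_k2, X) == pytest.approx(
            brute_force_loglik(printed_k2, X), abs=1e-8)

    @pytest.mark.parametrize("k,t", [(1, 4), (2, 3), (3, 4), (3, 2)])
    def test_matches_path_enumeration_randomized(self, k, t):
        rng = np.random.default_rng(100 * k + t)
        for rep in range(5):
            model = random_model(rng, k)
            X = rng.uniform(-80, 80, size=(t, 2))
            assert log_likelihood(model, X) == pytest.approx(
                brute_force_loglik(model, X), abs=1e-8)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        model = random_model(rng, 3)
        X = rng.uniform(-50, 50, size=(6, 2))
        perm = model.permuted([2, 0, 1])
        assert log_likelihood(model, X) == pytest.approx(
            log_likelihood(perm, X), abs=1e-9)

    def test_singular_covariance_raises(self):
        model = GaussianHMM(np.array([1.0]), np.array([[1.0]]),
                            np.zeros((1, 2)), np.zeros((1, 2, 2)))
        with pytest.raises(ModelDegeneracyError):
            log_likelihood(model, np.zeros((2, 2)))

    def test_empty_sequence_raises(self, printed_k2):
        with pytest.raises(InputError):
            log_likelihood(printed_k2, np.zeros((0, 2)))


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

class TestDecode:
    def test_k1_all_same_label(self):
        model = GaussianHMM(np.array([1.0]), np.array([[1.0]]),
                            np.zeros((1, 2)), np.eye(2)[None] * 30)
        path = decode_rois(model, np.random.default_rng(0).normal(size=(5, 2)))
        assert np.all(path == 0)

    def test_matches_enumeration(self, printed_k2):
        rng = np.random.default_rng(12)
        for rep in range(5):
            X = rng.uniform(-40, 40, size=(3, 2))
            assert tuple(decode_rois(printed_k2, X)) == brute_force_viterbi(
                printed_k2, X)

    def test_symmetric_tie_goes_to_lower_index(self):
        # two identical ROIs, uniform prior/transitions: every path ties
        model = GaussianHMM(np.array([0.5, 0.5]),
                            np.full((2, 2), 0.5),
                            np.zeros((2, 2)),
                            np.stack([np.eye(2) * 10] * 2))
        path = decode_rois(model, np.zeros((3, 2)))
        assert np.all(path == 0)

    def test_length_matches_input(self, separated_three_roi):
        seqs = sample_sequences(separated_three_roi, 3, 7, seed=5)
        for s in seqs:
            assert decode_rois(separated_three_roi, s).shape == (7,)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

class TestSampling:
    def test_deterministic_model_forces_path(self):
        model = GaussianHMM(
            prior=np.array([1.0, 0.0]),
            transitions=np.array([[0.0, 1.0], [0.0, 1.0]]),
            means=np.array([[-50.0, 0.0], [50.0, 0.0]]),
            covariances=np.stack([np.eye(2) * 1e-6] * 2),
        )
        (s,) = sample_sequences(model, 1, 4, seed=3)
        np.testing.assert_allclose(
            s.positions, [[-50, 0], [50, 0], [50, 0], [50, 0]], atol=0.05)

    def test_occupancy_matches_marginal_distribution(self, separated_three_roi):
        m = separated_three_roi
        seqs = sample_sequences(m, 1000, 10, seed=11)
        labels = np.concatenate([decode_rois(m, s) for s in seqs])
        occ = np.bincount(labels, minlength=3) / labels.size
        # marginal state distribution averaged over the 10 steps
        marg = np.zeros(3)
        p = m.prior.copy()
        for _ in range(10):
            marg += p
            p = p @ m.transitions
        marg /= 10
        assert np.all(np.abs(occ - marg) < 0.02)

    def test_same_seed_identical(self, separated_three_roi):
        a = sample_sequences(separated_three_roi, 5, 6, seed=9)
        b = sample_sequences(separated_three_roi, 5, 6, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.fixations, y.fixations)

    def test_zero_length_distribution_rejected(self, separated_three_roi):
        with pytest.raises(InputError):
            sample_sequences(separated_three_roi, 2, lambda rng: 0, seed=1)


# ---------------------------------------------------------------------------
# VBEM fitting
# ---------------------------------------------------------------------------

class TestVBEM:
    def test_k1_matches_closed_form_gaussian_posterior(self):
        """K=1 collapses to a Bayes-estimated single Gaussian: the VBEM result
        must match the conjugate Normal-Wishart posterior computed by hand."""
        rng = np.random.default_rng(21)
        X = rng.normal([10.0, -5.0], [12.0, 9.0], size=(400, 2))
        seqs = [_seq(X[i * 10:(i + 1) * 10]) for i in range(40)]
        hyper = VBHyper()
        res = fit_vbem(seqs, 1, hyper, n_restarts=1, seed=0)
        # closed-form Normal-(inverse-)Wishart update
        n = X.shape[0]
        beta0 = hyper.mean_prior_strength
        m0 = np.asarray(hyper.mean_prior_center)
        nu0 = hyper.covariance_prior_dof
        S0inv = np.asarray(hyper.covariance_prior_scale) * (nu0 - 3.0)
        xbar = X.mean(axis=0)
        S = np.cov(X.T, bias=True) * n
        mean_post = (beta0 * m0 + n * xbar) / (beta0 + n)
        d = (xbar - m0)[:, None]
        scale_post = S0inv + S + (beta0 * n / (beta0 + n)) * (d @ d.T)
        cov_post = scale_post / (nu0 + n - 3.0)  # inverse-Wishart mean, d=2
        np.testing.assert_allclose(res.model.means[0], mean_post, atol=1e-6)
        np.testing.assert_allclose(res.model.covariances[0], cov_post, rtol=1e-5)

    def test_recovers_separated_rois(self, separated_three_roi):
        seqs = sample_sequences(separated_three_roi, 60, 10, seed=31)
        res = fit_vbem(seqs, 3, n_restarts=3, seed=31)
        assert res.converged
        got = res.model.means
        # optimal label matching by nearest true center
        order = [int(np.argmin(np.linalg.norm(got - c, axis=1)))
                 for c in separated_three_roi.means]
        assert sorted(order) == [0, 1, 2]
        for i, c in enumerate(separated_three_roi.means):
            assert np.linalg.norm(got[order[i]] - c) < 5.0
        perm = res.model.permuted(order)
        tv = 0.5 * np.abs(perm.transitions - separated_three_roi.transitions).sum(axis=1)
        assert np.all(tv < 0.1)

    def test_duplicating_data_keeps_roi_means(self, separated_three_roi):
        seqs = sample_sequences(separated_three_roi, 30, 8, seed=41)
        a = fit_vbem(seqs, 3, n_restarts=2, seed=5).model
        b = fit_vbem(seqs + seqs, 3, n_restarts=2, seed=5).model
        ma = np.array(sorted(map(tuple, np.round(a.means, 1))))
        mb = np.array(sorted(map(tuple, np.round(b.means, 1))))
        np.testing.assert_allclose(ma, mb, atol=1.5)

    def test_reproducible_bit_for_bit(self, separated_three_roi):
        seqs = sample_sequences(separated_three_roi, 20, 8, seed=51)
        a = fit_vbem(seqs, 2, n_restarts=2, seed=17)
        b = fit_vbem(seqs, 2, n_restarts=2, seed=17)
        np.testing.assert_array_equal(a.model.means, b.model.means)
        assert a.lower_bound == b.lower_bound

    def test_model_satisfies_invariants(self, separated_three_roi):
        seqs = sample_sequences(separated_three_roi, 20, 8, seed=61)
        res = fit_vbem(seqs, 4, n_restarts=2, seed=3)
        res.model.validate()
        assert res.n_rois_selected == res.model.n_rois

    def test_too_many_rois_rejected(self, separated_three_roi):
        seqs = sample_sequences(separated_three_roi, 1, 3, seed=1)
        with pytest.raises(InputError):
            fit_vbem(seqs, 5, n_restarts=1, seed=0)


def test_lower_bound_monotone_within_run(separated_three_roi):
    """The variational lower bound never decreases across VBEM iterations."""
    from gazehmm.hmm import (
        VBHyper as _VB, _HyperArrays, _e_step, _elbo, _group_by_length,
        _init_posterior, _m_step)

    seqs = sample_sequences(separated_three_roi, 25, 8, seed=81)
    Xs = [s.positions for s in seqs]
    for K in (1, 2, 3):
        hy = _HyperArrays(_VB(), K)
        groups = _group_by_length(Xs)
        post = _init_posterior(Xs, K, hy, seed=4)
        prev = -np.inf
        for _ in range(40):
            sp, sA, Nk, xb, Sk, ell = _e_step(Xs, groups, post)
            bound = _elbo(post, hy, ell)
            assert bound >= prev - 1e-8
            prev = bound
            post = _m_step(sp, sA, Nk, xb, Sk, hy)


class TestSelectNRois:
    def test_single_candidate_equals_fit(self, separated_three_roi):
        seqs = sample_sequences(separated_three_roi, 15, 8, seed=71)
        a = select_n_rois(seqs, [2], n_restarts=2, seed=9)
        b = fit_vbem(seqs, 2, n_restarts=2, seed=9)
        assert a.lower_bound == b.lower_bound

    def test_selects_true_k_on_separated_data(self, separated_three_roi):
        hits = 0
        n_rep = 8
        for rep in range(n_rep):
            seqs = sample_sequences(separated_three_roi, 40, 10, seed=500 + rep)
            res = select_n_rois(seqs, range(1, 6), n_restarts=2, seed=rep)
            hits += res.n_rois_selected == 3
        assert hits >= int(0.8 * n_rep)

    def test_empty_range_rejected(self, separated_three_roi):
        seqs = sample_sequences(separated_three_roi, 5, 5, seed=0)
        with pytest.raises(InputError):
            select_n_rois(seqs, [], seed=0)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_json_round_trip(tmp_path, separated_three_roi):
    path = tmp_path / "model.json"
    separated_three_roi.save(path, provenance={"seed": 1})
    loaded = GaussianHMM.load(path)
    np.testing.assert_array_equal(loaded.prior, separated_three_roi.prior)
    np.testing.assert_array_equal(loaded.transitions, separated_three_roi.transitions)
    np.testing.assert_array_equal(loaded.means, separated_three_roi.means)
    np.testing.assert_array_equal(loaded.covariances, separated_three_roi.covariances)


def test_loglik_agrees_with_hmmlearn(printed_k2):
    """Cross-check the forward recursion against an independent implementation."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    ref = hmmlearn.GaussianHMM(n_components=2, covariance_type="full")
    ref.startprob_ = printed_k2.prior
    ref.transmat_ = printed_k2.transitions
    ref.means_ = printed_k2.means
    ref.covars_ = printed_k2.covariances
    rng = np.random.default_rng(3)
    X = rng.uniform(-40, 40, size=(12, 2))
    assert log_likelihood(printed_k2, X) == pytest.approx(ref.score(X), abs=1e-8)
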