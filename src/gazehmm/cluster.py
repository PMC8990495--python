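"""Clustering of individual HMMs into representative eye-movement patterns.

Individual fixation HMMs are grouped into a small number of representative
group HMMs by variational hierarchical EM over HMM mixtures: instead of
touching raw fixation data, the algorithm clusters the *models* directly,
using a closed-form variational lower bound on the expected log-likelihood of
sequences generated by one HMM under another.  Conceptually each input model
contributes a set of virtual sequences (their count and length are the
weighting parameters below); the expectations over those virtual samples are
evaluated analytically, so the procedure is deterministic given its
initialization.  The E-step soft-assigns whole models to clusters and builds
expected start/transition/occupancy statistics through state-correspondence
recursions; the M-step re-estimates each group HMM from those statistics in
closed form.

Face-recognition studies in this tradition conventionally fix two clusters —
an eyes-focused and a nose-/center-focused representative pattern — with the
group ROI count set to the median ROI count of the individual models.

Pattern separation ("do participants' data actually prefer their own
pattern?") is quantified by each participant's own-minus-other mean
log-likelihood margin and tested as a one-way group comparison of the
A-minus-B log-likelihood difference between the two assignment groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy import stats as sps
from sklearn.cluster import KMeans

from .exceptions import DegenerateVarianceError, InputError
from .hmm import GaussianHMM, _DIM, mean_log_likelihood


@dataclass
class ClusterConfig:
    """Settings of the hierarchical EM clustering.

    ``n_virtual_samples`` and ``virtual_length`` parameterize the virtual
    sample set each input model stands for: the length sets the horizon of
    the state-correspondence recursion and the count scales each model's
    weight in the cluster responsibilities.
    """

    n_virtual_samples: int = 1000
    virtual_length: int = 10
    n_restarts: int = 5
    max_iter: int = 200
    tol: float = 1e-7
    #: Dirichlet pseudocount regularizing group prior/transition estimates.
    pseudocount: float = 1.0
    #: Small ridge (px^2) keeping group ROI covariances positive-definite.
    cov_ridge: float = 1.0
    #: Maximum re-initializations of an emptied cluster before flagging.
    max_reinit: int = 3


@dataclass
class ClusterResult:
    """Group HMMs plus hard/soft assignments of the input models."""

    group_models: list[GaussianHMM]
    assignments: np.ndarray          # (M,) hard cluster index per input model
    responsibilities: np.ndarray     # (M, C)
    objective: float
    degenerate: bool = False


@dataclass
class PatternPair:
    """Two representative patterns (A, B) with participant assignments."""

    pattern_a: GaussianHMM
    pattern_b: GaussianHMM
    assignments: dict[str, str]      # participant_id -> "A" | "B"
    n_group_rois: int
    degenerate: bool = False

    def pattern(self, label: str) -> GaussianHMM:
        return self.pattern_a if label == "A" else self.pattern_b


@dataclass
class SeparationResult:
    """Own-vs-other pattern log-likelihood margins and their group test."""

    per_participant_margin: dict[str, float]
    f_stat: float
    df: tuple[int, int]
    p_value: float
    effect_size: float
    effect_ci: tuple[float, float]


def median_roi_count(models: Sequence[GaussianHMM]) -> int:
    """Integer median of the models' ROI counts, rounding half-integers up."""
    if not models:
        raise InputError("need at least one model")
    return int(math.ceil(np.median([m.n_rois for m in models])))


# ---------------------------------------------------------------------------
# closed-form expectations between Gaussian HMMs
# ---------------------------------------------------------------------------

def _expected_gauss_ll(src: GaussianHMM, dst: GaussianHMM) -> np.ndarray:
    """E_{x ~ src state rho}[log N(x; dst state beta)], shape (K_src, K_dst)."""
    Ks, Kd = src.n_rois, dst.n_rois
    out = np.empty((Ks, Kd))
    for b in range(Kd):
        inv = np.linalg.inv(dst.covariances[b])
        _, logdet = np.linalg.slogdet(dst.covariances[b])
        for r in range(Ks):
            diff = src.means[r] - dst.means[b]
            out[r, b] = -0.5 * (
                _DIM * np.log(2 * np.pi) + logdet
                + np.trace(inv @ src.covariances[r])
                + diff @ inv @ diff
            )
    return out


def _estep_pair(src: GaussianHMM, dst: GaussianHMM, tau: int):
    """Variational lower bound on the per-sequence expected log-likelihood of
    ``src``-generated length-``tau`` sequences under ``dst``, plus the
    expected statistics the group M-step needs.

    Returns ``(bound, start, xi_sum, omega)`` with shapes (), (K_dst,),
    (K_dst, K_dst) and (K_src, K_dst).
    """
    Ks, Kd = src.n_rois, dst.n_rois
    ell = _expected_gauss_ll(src, dst)                 # (Ks, Kd)
    logA_d = np.log(np.clip(dst.transitions, 1e-300, None))
    logpi_d = np.log(np.clip(dst.prior, 1e-300, None))
    # backward recursion for the bound; keep the per-step log-sum terms to
    # recover the optimal variational transition distributions on the way up
    L = [None] * (tau + 1)
    L[tau] = ell
    for t in range(tau - 1, 0, -1):
        # S[r', b] = lse_{b'} (logA_d[b, b'] + L[t+1][r', b'])
        S = logsumexp(logA_d[None, :, :] + L[t + 1][:, None, :], axis=2)
        L[t] = ell + src.transitions @ S
    b0 = logsumexp(logpi_d[None, :] + L[1], axis=1)    # (Ks,)
    bound = float(src.prior @ b0)

    # forward accumulation of expected counts under the optimal variational
    # correspondence distributions
    phi1 = np.exp(logpi_d[None, :] + L[1] - b0[:, None])        # (Ks, Kd)
    nu = src.prior[:, None] * phi1                               # (Ks, Kd)
    start = nu.sum(axis=0)
    omega = nu.copy()
    xi_sum = np.zeros((Kd, Kd))
    for t in range(2, tau + 1):
        # phi_t[r', b, b'] = softmax_{b'}(logA_d[b, b'] + L[t][r', b'])
        logits = logA_d[None, :, :] + L[t][:, None, :]
        logits -= logsumexp(logits, axis=2, keepdims=True)
        phi = np.exp(logits)
        temp = src.transitions.T @ nu                            # (Ks', Kd=b)
        nu = np.einsum("rb,rbc->rc", temp, phi)
        xi_sum += np.einsum("rb,rbc->bc", temp, phi)
        omega += nu
    return bound, start, xi_sum, omega


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def _estep_batch(models: Sequence[GaussianHMM], dst: GaussianHMM, tau: int):
    """Vectorized :func:`_estep_pair` over models sharing a state count.

    Returns ``(bounds, starts, xi_sums, omegas)`` with a leading batch axis.
    """
    B = len(models)
    Ks = models[0].n_rois
    Kd = dst.n_rois
    pri = np.stack([m.prior for m in models])                  # (B, Ks)
    trans = np.stack([m.transitions for m in models])          # (B, Ks, Ks)
    mus = np.stack([m.means for m in models])                  # (B, Ks, 2)
    covs = np.stack([m.covariances for m in models])           # (B, Ks, 2, 2)

    inv = np.linalg.inv(dst.covariances)                       # (Kd, 2, 2)
    _, logdet = np.linalg.slogdet(dst.covariances)             # (Kd,)
    diff = mus[:, :, None, :] - dst.means[None, None, :, :]    # (B, Ks, Kd, 2)
    quad = np.einsum("brki,kij,brkj->brk", diff, inv, diff)
    tr = np.einsum("kij,brji->brk", inv, covs)
    ell = -0.5 * (_DIM * np.log(2 * np.pi) + logdet[None, None, :] + tr + quad)

    logA_d = np.log(np.clip(dst.transitions, 1e-300, None))
    logpi_d = np.log(np.clip(dst.prior, 1e-300, None))
    L = [None] * (tau + 1)
    L[tau] = ell
    for t in range(tau - 1, 0, -1):
        S = _lse(logA_d[None, None, :, :] + L[t + 1][:, :, None, :], 3)
        L[t] = ell + np.einsum("brq,bqk->brk", trans, S)
    b0 = _lse(logpi_d[None, None, :] + L[1], 2)                # (B, Ks)
    bounds = np.einsum("br,br->b", pri, b0)

    phi1 = np.exp(logpi_d[None, None, :] + L[1] - b0[:, :, None])
    nu = pri[:, :, None] * phi1                                # (B, Ks, Kd)
    starts = nu.sum(axis=1)
    omegas = nu.copy()
    xi_sums = np.zeros((B, Kd, Kd))
    for t in range(2, tau + 1):
        logits = logA_d[None, None, :, :] + L[t][:, :, None, :]
        logits -= logits.max(axis=3, keepdims=True)
        phi = np.exp(logits)
        phi /= phi.sum(axis=3, keepdims=True)                  # (B, Ks', Kd, Kd)
        temp = np.einsum("brq,brk->bqk", trans, nu)            # (B, Ks', Kd)
        nu = np.einsum("brk,brkc->brc", temp, phi)
        xi_sums += np.einsum("brk,brkc->bkc", temp, phi)
        omegas += nu
    return bounds, starts, xi_sums, omegas


def _estep_all(models, dst: GaussianHMM, tau: int) -> list:
    """Batch the E-step over a heterogeneous model list, grouped by K."""
    byk: dict[int, list[int]] = {}
    for i, m in enumerate(models):
        byk.setdefault(m.n_rois, []).append(i)
    out: list = [None] * len(models)
    for _, idxs in byk.items():
        bounds, starts, xis, omegas = _estep_batch(
            [models[i] for i in idxs], dst, tau)
        for j, i in enumerate(idxs):
            out[i] = (float(bounds[j]), starts[j], xis[j], omegas[j])
    return out


def _log_param_prior(group: GaussianHMM, cfg: ClusterConfig) -> float:
    """Dirichlet / inverse-Wishart-style penalties matching the M-step."""
    a = cfg.pseudocount
    val = a * np.sum(np.log(np.clip(group.prior, 1e-300, None)))
    val += a * np.sum(np.log(np.clip(group.transitions, 1e-300, None)))
    for c in group.covariances:
        _, logdet = np.linalg.slogdet(c)
        val += -0.5 * cfg.cov_ridge * np.trace(np.linalg.inv(c)) - 0.5 * logdet
    return float(val)


def _m_step_group(models, weights, stats, cfg: ClusterConfig, K: int) -> GaussianHMM:
    """Closed-form MAP update of one group HMM from expected statistics."""
    pi = np.full(K, cfg.pseudocount)
    A = np.full((K, K), cfg.pseudocount)
    W = np.zeros(K)
    mu_acc = np.zeros((K, _DIM))
    for m, w, (bound, start, xi, omega) in zip(models, weights, stats):
        pi += w * start
        A += w * xi
        W += w * omega.sum(axis=0)
        mu_acc += w * (omega.T @ m.means)
    W_safe = np.maximum(W, 1e-12)
    mu = mu_acc / W_safe[:, None]
    covs = np.zeros((K, _DIM, _DIM))
    for m, w, (bound, start, xi, omega) in zip(models, weights, stats):
        for b in range(K):
            diff = m.means - mu[b]                       # (Ks, 2)
            covs[b] += w * np.einsum(
                "r,rij->ij", omega[:, b],
                m.covariances + np.einsum("ri,rj->rij", diff, diff))
    for b in range(K):
        covs[b] = (covs[b] + cfg.cov_ridge * np.eye(_DIM)) / (W_safe[b] + 1.0)
    return GaussianHMM(
        prior=pi / pi.sum(),
        transitions=A / A.sum(axis=1, keepdims=True),
        means=mu,
        covariances=covs,
    )


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _global_group(models, K: int, cfg: ClusterConfig, rng) -> GaussianHMM:
    """A single group capturing the ROI geometry pooled over all models."""
    means, covs, wts = [], [], []
    for m in models:
        # occupancy-weight each ROI by the model's average state distribution
        occ = np.zeros(m.n_rois)
        p = m.prior.copy()
        for _ in range(cfg.virtual_length):
            occ += p
            p = p @ m.transitions
        occ /= cfg.virtual_length
        means.append(m.means)
        covs.append(m.covariances)
        wts.append(occ)
    means = np.concatenate(means)
    covs = np.concatenate(covs)
    wts = np.concatenate(wts)
    if means.shape[0] > K:
        km = KMeans(n_clusters=K, n_init=2,
                    random_state=int(rng.integers(0, 2**31)))
        labels = km.fit_predict(means, sample_weight=wts + 1e-9)
    else:
        labels = np.arange(means.shape[0]) % K
    g_means = np.zeros((K, _DIM))
    g_covs = np.zeros((K, _DIM, _DIM))
    for k in range(K):
        sel = labels == k
        if not np.any(sel):
            sel = np.ones(means.shape[0], dtype=bool)
        w = wts[sel] + 1e-9
        mu = np.average(means[sel], axis=0, weights=w)
        d = means[sel] - mu
        g_means[k] = mu
        g_covs[k] = (
            np.einsum("r,rij->ij", w, covs[sel])
            + np.einsum("r,ri,rj->ij", w, d, d)
        ) / w.sum() + cfg.cov_ridge * np.eye(_DIM)
    return GaussianHMM(
        prior=np.full(K, 1.0 / K),
        transitions=np.full((K, K), 1.0 / K),
        means=g_means,
        covariances=g_covs,
    )


def _init_groups(models, C: int, K: int, cfg: ClusterConfig, rng) -> list[GaussianHMM]:
    """Initial clusters from k-means on per-model dynamics fingerprints.

    All models share the global group's emission layout; each model's
    expected start/transition statistics under it form a fingerprint that
    separates models differing in scanpath dynamics even when their ROI
    geometry is nearly identical.
    """
    M = len(models)
    glob = _global_group(models, K, cfg, rng)
    stats = _estep_all(models, glob, cfg.virtual_length)
    feats = np.stack([
        np.concatenate([
            (s[1] + cfg.pseudocount) / (s[1].sum() + K * cfg.pseudocount),
            ((s[2] + cfg.pseudocount)
             / (s[2] + cfg.pseudocount).sum(axis=1, keepdims=True)).ravel(),
        ])
        for s in stats
    ])
    if M > C:
        km = KMeans(n_clusters=C, n_init=4,
                    random_state=int(rng.integers(0, 2**31)))
        labels = km.fit_predict(feats)
    else:
        labels = np.arange(M) % C
    groups = []
    for c in range(C):
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            members = np.array([int(rng.integers(0, M))])
        groups.append(_m_step_group(
            [models[i] for i in members],
            np.ones(members.size),
            [stats[i] for i in members],
            cfg, K))
    return groups


# ---------------------------------------------------------------------------
# main EM loop
# ---------------------------------------------------------------------------

def _hem_run(models, C: int, K: int, cfg: ClusterConfig, rng) -> ClusterResult:
    M = len(models)
    tau = cfg.virtual_length
    N = float(cfg.n_virtual_samples)
    groups = _init_groups(models, C, K, cfg, rng)
    log_omega = np.full(C, -np.log(C))
    prev = -np.inf
    degenerate = False
    reinits = 0
    resp = np.full((M, C), 1.0 / C)
    for _ in range(cfg.max_iter):
        stats = [_estep_all(models, g, tau) for g in groups]
        bounds = np.array([[s[0] for s in col] for col in stats]).T  # (M, C)
        joint = log_omega[None, :] + N * bounds
        norm = logsumexp(joint, axis=1)
        resp = np.exp(joint - norm[:, None])
        objective = norm.sum() + sum(_log_param_prior(g, cfg) for g in groups)
        weight = resp.sum(axis=0)
        if weight.min() < 0.5 and reinits < cfg.max_reinit:
            # restart the emptied cluster from the worst-explained model
            worst = int(np.argmin(weight))
            loser = int(np.argmin(norm))
            groups[worst] = _m_step_group(
                [models[loser]], np.ones(1),
                [_estep_pair(models[loser], groups[worst], tau)], cfg, K)
            reinits += 1
            prev = -np.inf
            continue
        if weight.min() < 0.5:
            degenerate = True
        if np.isfinite(prev) and objective - prev < cfg.tol * max(1.0, abs(objective)):
            prev = max(prev, objective)
            break
        prev = objective
        log_omega = np.log(np.clip(weight / weight.sum(), 1e-12, None))
        for c in range(C):
            groups[c] = _m_step_group(
                models, N * resp[:, c], stats[c], cfg, K)
    hard = np.argmax(resp, axis=1)  # np.argmax ties -> lowest index (cluster A)
    if not degenerate and len(set(hard.tolist())) < C:
        degenerate = True
    if degenerate:
        # a persistently empty cluster carries no information: mirror the
        # dominant cluster's model so the result stays well-formed
        weight = resp.sum(axis=0)
        main = int(np.argmax(weight))
        for c in range(C):
            if weight[c] < 0.5:
                src = groups[main]
                groups[c] = GaussianHMM(src.prior.copy(), src.transitions.copy(),
                                        src.means.copy(), src.covariances.copy())
    return ClusterResult(
        group_models=groups,
        assignments=hard,
        responsibilities=resp,
        objective=float(prev),
        degenerate=degenerate,
    )


def cluster_vhem(
    models: Sequence[GaussianHMM],
    n_clusters: int = 2,
    n_group_rois: int | None = None,
    config: ClusterConfig | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Cluster individual HMMs into ``n_clusters`` representative group HMMs.

    Returns the best of ``config.n_restarts`` seeded restarts by the
    (penalized) expected log-likelihood objective.  Hard assignments are the
    responsibility arg-max with ties resolved toward the first cluster.
    Clusters that empty out are re-initialized; if the degeneracy persists
    (e.g. all input models identical), the result carries ``degenerate=True``.
    """
    if len(models) < n_clusters:
        raise InputError("need at least as many models as clusters")
    if n_group_rois is None:
        n_group_rois = median_roi_count(models)
    if n_group_rois < 1:
        raise InputError("n_group_rois must be >= 1")
    cfg = config or ClusterConfig()
    for m in models:
        m.validate()
    # run in a canonical model order so the outcome does not depend on the
    # order in which callers list the models (up to cluster relabeling)
    keys = [
        np.round(np.concatenate([m.prior, m.transitions.ravel(),
                                 m.means.ravel(), m.covariances.ravel()]), 9)
        .tobytes()
        for m in models
    ]
    order = sorted(range(len(models)), key=lambda i: (keys[i], i))
    inverse = np.argsort(order)
    canon = [models[i] for i in order]
    rng = np.random.default_rng(seed)
    best: ClusterResult | None = None
    for _ in range(cfg.n_restarts):
        res = _hem_run(canon, n_clusters, n_group_rois, cfg, rng)
        if best is None or res.objective > best.objective:
            best = res
    best.assignments = best.assignments[inverse]
    best.responsibilities = best.responsibilities[inverse]
    return best


def as_pattern_pair(
    result: ClusterResult, participant_ids: Sequence[str]
) -> PatternPair:
    """Label a two-cluster result as Patterns A and B.

    Pattern A is the group HMM with the higher conditional entropy of the
    second fixation given the first — the broader, more exploratory pattern —
    and Pattern B the more consistent (typically eyes-focused) one, matching
    the convention of face-recognition studies with this method.  Exact ties
    fall back to cluster size, then to the cluster of the first model, so the
    labelling is deterministic.
    """
    from .metrics import fixation_entropies  # local import to avoid a cycle

    if len(result.group_models) != 2:
        raise InputError("pattern pair requires exactly two clusters")
    if len(participant_ids) != result.assignments.shape[0]:
        raise InputError("one participant id per clustered model is required")
    h = [fixation_entropies(m).h2_given_1 for m in result.group_models]
    sizes = np.bincount(result.assignments, minlength=2)
    if abs(h[0] - h[1]) > 1e-12:
        order = [0, 1] if h[0] > h[1] else [1, 0]
    elif sizes[0] != sizes[1]:
        order = [0, 1] if sizes[0] > sizes[1] else [1, 0]
    else:
        first = int(result.assignments[0])
        order = [first, 1 - first]
    labels = {order[0]: "A", order[1]: "B"}
    return PatternPair(
        pattern_a=result.group_models[order[0]],
        pattern_b=result.group_models[order[1]],
        assignments={
            str(pid): labels[int(c)]
            for pid, c in zip(participant_ids, result.assignments)
        },
        n_group_rois=result.group_models[0].n_rois,
        degenerate=result.degenerate,
    )


def pattern_separation(
    sequences_by_participant: Mapping[str, Sequence],
    pattern_pair: PatternPair,
) -> SeparationResult:
    """Test that participants' data prefer their own representative pattern.

    For every participant the mean per-sequence log-likelihood is computed
    under both patterns.  The margin is own-pattern minus other-pattern; the
    F statistic is the one-way comparison of the A-minus-B difference between
    the two assignment groups, reported with partial eta-squared and its 90%
    noncentrality-inversion CI.
    """
    from .stats import eta_squared_ci  # local import to avoid a cycle

    margins: dict[str, float] = {}
    diffs_a, diffs_b = [], []
    for pid, label in pattern_pair.assignments.items():
        seqs = sequences_by_participant.get(pid)
        if not seqs:
            raise InputError(f"participant {pid!r} has no sequences")
        la = mean_log_likelihood(pattern_pair.pattern_a, seqs)
        lb = mean_log_likelihood(pattern_pair.pattern_b, seqs)
        margins[pid] = (la - lb) if label == "A" else (lb - la)
        (diffs_a if label == "A" else diffs_b).append(la - lb)
    if len(diffs_a) < 2 or len(diffs_b) < 2:
        raise DegenerateVarianceError(
            "pattern separation needs at least two participants per pattern"
        )
    a = np.asarray(diffs_a)
    b = np.asarray(diffs_b)
    n = a.size + b.size
    grand = (a.sum() + b.sum()) / n
    ss_between = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df1, df2 = 1, n - 2
    if ss_within <= 0:
        f = 0.0 if ss_between <= 0 else np.inf
        p = 1.0 if ss_between <= 0 else 0.0
    else:
        f = float(ss_between / df1 / (ss_within / df2))
        p = float(sps.f.sf(f, df1, df2))
    eta = float(f * df1 / (f * df1 + df2)) if np.isfinite(f) else 1.0
    ci = eta_squared_ci(f, df1, df2, level=0.90) if np.isfinite(f) else (1.0, 1.0)
    return SeparationResult(
        per_participant_margin=margins,
        f_stat=f,
        df=(df1, df2),
        p_value=p,
        effect_size=eta,
        effect_ci=ci,
    )
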