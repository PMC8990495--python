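"""Quantification of individual eye-movement patterns and consistency.

Two families of metrics:

* **A–B scale** — where a participant-condition's data fall on the continuum
  between the two representative patterns:
  ``(A - B) / (|A| + |B|)`` with ``A`` and ``B`` the mean per-sequence
  log-likelihoods of the data under the Pattern-A and Pattern-B group HMMs.
  Positive values indicate greater similarity to Pattern A.  Means (rather
  than sums) are used so the scale is comparable across unequal trial counts.

* **Fixation entropies** — consistency of early fixations, computed from the
  fitted model parameters: the marginal entropy of the first fixation's ROI
  (from the prior vector) and the conditional entropies of the second ROI
  given the first and of the third given the second (from the transition
  rows, weighted by the ROI distribution at the conditioning step).  Lower
  entropy means more consistent, more predictable gaze behavior.  Bits by
  default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InputError
from .hmm import GaussianHMM, mean_log_likelihood


@dataclass
class ABScore:
    """Position on the Pattern-A-vs-Pattern-B continuum, in [-1, 1]."""

    value: float
    ll_a: float
    ll_b: float
    degenerate: bool = False


@dataclass
class EntropyProfile:
    """Marginal and conditional entropies of the first three fixations."""

    h1: float
    h2_given_1: float
    h3_given_2: float


def ab_scale(
    seqs: Sequence,
    pattern_a: GaussianHMM,
    pattern_b: GaussianHMM,
) -> ABScore:
    """Score a participant-condition's sequences on the A–B scale."""
    if not seqs:
        raise InputError("need at least one sequence")
    pattern_a.validate()
    pattern_b.validate()
    ll_a = mean_log_likelihood(pattern_a, seqs)
    ll_b = mean_log_likelihood(pattern_b, seqs)
    denom = abs(ll_a) + abs(ll_b)
    if denom == 0.0:
        return ABScore(value=0.0, ll_a=ll_a, ll_b=ll_b, degenerate=True)
    return ABScore(value=(ll_a - ll_b) / denom, ll_a=ll_a, ll_b=ll_b)


def _entropy(p: np.ndarray, base: str) -> np.ndarray:
    """Row entropies with the 0 log 0 := 0 convention."""
    p = np.asarray(p, dtype=float)
    logs = np.where(p > 0, np.log(np.clip(p, 1e-300, None)), 0.0)
    h = -np.sum(p * logs, axis=-1) + 0.0  # avoid -0.0 for deterministic rows
    if base == "bits":
        h = h / np.log(2.0)
    elif base != "nats":
        raise InputError("entropy base must be 'bits' or 'nats'")
    return h


def fixation_entropies(model: GaussianHMM, base: str = "bits") -> EntropyProfile:
    """Entropy profile of the first three fixations implied by the model.

    h1 is the entropy of the prior; h2|1 averages transition-row entropies
    under the prior; h3|2 averages them under the one-step ROI distribution
    (prior times transition matrix).
    """
    model.validate()
    pi = model.prior
    A = model.transitions
    row_h = _entropy(A, base)
    return EntropyProfile(
        h1=float(_entropy(pi, base)),
        h2_given_1=float(pi @ row_h),
        h3_given_2=float((pi @ A) @ row_h),
    )
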