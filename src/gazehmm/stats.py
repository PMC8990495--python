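"""Behavioral statistics: signal detection, within-subject contrasts,
correlations, and regression power analysis.

Recognition memory performance is summarized with equal-variance signal
detection theory: sensitivity ``d' = z(H) - z(F)`` and criterion
``c = -(z(H) + z(F)) / 2`` from hit and false-alarm rates, with the 1/(2n)
correction for perfect rates by default.

The factorial design (mask condition at learning x mask condition at
recognition, both within subject) is analyzed with difference-score
contrasts: every effect of a 2x2 within design is a paired t test on the
appropriate per-participant contrast, and its F equals t^2 exactly.  Effect
sizes follow the conventional reporting shape: Cohen's d with a 95% CI
(noncentral-t inversion) for paired contrasts, partial eta-squared with a
90% CI (noncentral-F inversion) for ANOVA effects.

Correlations between strategy change and performance change are Pearson r,
optionally partialled for covariates by the residual method (both variables
regressed on the covariates; r of the residuals, with df reduced by the
number of covariates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .exceptions import (
    DegenerateVarianceError,
    InputError,
    UnreachablePowerError,
)

CONDITION_ORDER = [
    ("unmasked", "unmasked"),
    ("unmasked", "masked"),
    ("masked", "unmasked"),
    ("masked", "masked"),
]


@dataclass(frozen=True)
class ResponseCounts:
    """Old/new response counts of one participant-condition."""

    n_old: int
    hits: int
    n_new: int
    false_alarms: int

    def __post_init__(self) -> None:
        if self.n_old < 1 or self.n_new < 1:
            raise InputError("need at least one old and one new trial")
        if not 0 <= self.hits <= self.n_old:
            raise InputError("hits must lie in [0, n_old]")
        if not 0 <= self.false_alarms <= self.n_new:
            raise InputError("false_alarms must lie in [0, n_new]")


@dataclass
class PerformanceSummary:
    """Per-condition recognition performance."""

    dprime: float
    criterion: float
    mean_correct_rt: float | None = None
    condition: tuple[str, str] | None = None


@dataclass
class StatResult:
    """A test statistic in the conventional reporting shape."""

    statistic: float
    df: tuple[int, ...]
    p_value: float
    effect_size: float
    effect_ci: tuple[float, float]
    effect_name: str = "cohen_d"

    def report(self) -> str:
        dfs = ", ".join(str(d) for d in self.df)
        stat_name = "F" if self.effect_name.startswith("partial_eta") else "t"
        level = 90 if self.effect_name.startswith("partial_eta") else 95
        return (
            f"{stat_name}({dfs}) = {self.statistic:.3f}, p = {self.p_value:.4g}, "
            f"{self.effect_name} = {self.effect_size:.3f}, "
            f"{level}% CI [{self.effect_ci[0]:.4f}, {self.effect_ci[1]:.4f}]"
        )


# ---------------------------------------------------------------------------
# signal detection
# ---------------------------------------------------------------------------

def dprime(counts: ResponseCounts, correction: str = "half_count") -> PerformanceSummary:
    """Sensitivity and criterion from hit/false-alarm counts.

    Under ``correction="half_count"`` rates of 0 or 1 are replaced by
    ``1/(2n)`` and ``1 - 1/(2n)``; with ``correction="none"``, extreme rates
    raise an explicit error because the z transform diverges.
    """
    H = counts.hits / counts.n_old
    F = counts.false_alarms / counts.n_new
    if correction == "half_count":
        if H == 0.0:
            H = 1.0 / (2 * counts.n_old)
        elif H == 1.0:
            H = 1.0 - 1.0 / (2 * counts.n_old)
        if F == 0.0:
            F = 1.0 / (2 * counts.n_new)
        elif F == 1.0:
            F = 1.0 - 1.0 / (2 * counts.n_new)
    elif correction == "none":
        if H in (0.0, 1.0) or F in (0.0, 1.0):
            raise DegenerateVarianceError(
                "hit or false-alarm rate of 0 or 1 gives an infinite z score; "
                "use correction='half_count'"
            )
    else:
        raise InputError(f"unknown correction {correction!r}")
    zh, zf = sps.norm.ppf(H), sps.norm.ppf(F)
    return PerformanceSummary(dprime=float(zh - zf), criterion=float(-(zh + zf) / 2.0))


# ---------------------------------------------------------------------------
# effect-size confidence intervals
# ---------------------------------------------------------------------------

def _ncp_from_t(t_obs: float, df: int, prob: float) -> float:
    """Noncentrality delta with P(T_{df,delta} <= t_obs) = prob."""
    f = lambda d: sps.nct.cdf(t_obs, df, d) - prob
    lo, hi = t_obs - 2, t_obs + 2
    while f(lo) < 0:
        lo -= 5
    while f(hi) > 0:
        hi += 5
    return float(optimize.brentq(f, lo, hi, xtol=1e-8))


def cohen_d_ci(t_obs: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """CI for a paired-design Cohen's d by noncentral-t inversion."""
    df = n - 1
    a = (1.0 - level) / 2.0
    lo = _ncp_from_t(t_obs, df, 1.0 - a) / np.sqrt(n)
    hi = _ncp_from_t(t_obs, df, a) / np.sqrt(n)
    return (float(lo), float(hi))


def eta_squared_ci(
    f_obs: float, df1: int, df2: int, level: float = 0.90
) -> tuple[float, float]:
    """CI for partial eta-squared by noncentral-F inversion.

    The noncentrality bounds are converted with
    ``eta_p^2 = lambda / (lambda + df1 + df2 + 1)``.
    """
    a = (1.0 - level) / 2.0
    N = df1 + df2 + 1

    def bound(prob: float) -> float:
        if sps.f.cdf(f_obs, df1, df2) < prob:  # lambda = 0 already too extreme
            return 0.0
        g = lambda lam: sps.ncf.cdf(f_obs, df1, df2, lam) - prob
        hi = 10.0
        while g(hi) > 0:
            hi *= 2
            if hi > 1e7:
                break
        return float(optimize.brentq(g, 0.0, hi, xtol=1e-8))

    lam_lo = bound(1.0 - a)
    lam_hi = bound(a)
    return (lam_lo / (lam_lo + N), lam_hi / (lam_hi + N))


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def paired_contrast(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Paired t test of x vs y with Cohen's d (mean diff / sd of diffs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise InputError("need two equal-length paired vectors of size >= 3")
    d = x - y
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0.0:
        if np.allclose(d, 0.0):
            return StatResult(0.0, (n - 1,), 1.0, 0.0, (0.0, 0.0))
        raise DegenerateVarianceError("differences have zero variance")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), n - 1))
    cd = float(d.mean() / sd)
    return StatResult(t, (n - 1,), p, cd, cohen_d_ci(t, n))


def _anova_effect(diff: np.ndarray) -> StatResult:
    """Within-subject effect from its per-participant difference scores."""
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0.0:
        return StatResult(0.0, (1, n - 1), 1.0, 0.0, (0.0, 0.0),
                          effect_name="partial_eta_sq")
    t = diff.mean() / (sd / np.sqrt(n))
    f = float(t * t)
    df1, df2 = 1, n - 1
    p = float(sps.f.sf(f, df1, df2))
    eta = f / (f + df2)
    return StatResult(f, (df1, df2), p, float(eta),
                      eta_squared_ci(f, df1, df2), effect_name="partial_eta_sq")


def rm_anova_2x2(cells: pd.DataFrame | np.ndarray) -> dict[str, StatResult]:
    """2x2 fully-within ANOVA via difference-score contrasts.

    ``cells`` holds one row per participant and four columns ordered as
    (learn unmasked, recog unmasked), (unmasked, masked), (masked, unmasked),
    (masked, masked) — i.e. recognition mask varies fastest.  A DataFrame may
    use any column names in that order.  Every participant must have all four
    cells; missing values raise rather than impute.

    Returns the learning-mask and recognition-mask main effects and their
    interaction.  Each F is exactly the square of the paired t on the
    corresponding difference scores.
    """
    arr = np.asarray(cells, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise InputError("cells must be (n_participants, 4)")
    if arr.shape[0] < 2:
        raise InputError("need at least two participants")
    if not np.all(np.isfinite(arr)):
        raise InputError("missing or non-finite cells; no imputation is performed")
    uu, um, mu, mm = arr.T
    return {
        "learning_mask": _anova_effect((mu + mm) / 2.0 - (uu + um) / 2.0),
        "recognition_mask": _anova_effect((um + mm) / 2.0 - (uu + mu) / 2.0),
        "interaction": _anova_effect((mm - mu) - (um - uu)),
    }


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    df: int
    p_value: float


def correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: pd.DataFrame | np.ndarray | None = None,
) -> CorrelationResult:
    """Pearson or partial correlation (residual method).

    With covariates, both x and y are linearly regressed on the covariates
    (with intercept) and the Pearson r of the residuals is reported with
    ``df = n - 2 - n_covariates``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be equal-length vectors")
    n = x.size
    k = 0
    if covariates is not None:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != n:
            raise InputError("covariates must have one row per observation")
        k = Z.shape[1]
    if n < 4 + k:
        raise InputError(f"need at least {4 + k} observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("missing values are not supported")
    if x.std() == 0.0 or y.std() == 0.0:
        raise DegenerateVarianceError("constant input vector")
    if covariates is not None:
        design = np.column_stack([np.ones(n), Z])
        x = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        y = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        if x.std() == 0.0 or y.std() == 0.0:
            raise DegenerateVarianceError("a variable is fully explained by covariates")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2 - k
    r_clip = min(max(r, -0.9999999999), 0.9999999999)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(r=r, df=df, p_value=p)


# ---------------------------------------------------------------------------
# simple derived measures and power analysis
# ---------------------------------------------------------------------------

def flanker_effect(incongruent: float, congruent: float) -> float:
    """Normalized congruency effect (I - C) / (I + C), in (-1, 1)."""
    if incongruent <= 0 or congruent <= 0:
        raise InputError("performance measures must be positive")
    return (incongruent - congruent) / (incongruent + congruent)


def regression_power(f2: float, n_predictors: int, n: int, alpha: float = 0.05) -> float:
    """Power of the fixed-effects F test of R^2 at sample size n.

    Numerator df is the predictor count, denominator df is ``n - p - 1``, and
    the noncentrality is ``f2 * n``.
    """
    df2 = n - n_predictors - 1
    if df2 < 1:
        return 0.0
    fcrit = sps.f.ppf(1.0 - alpha, n_predictors, df2)
    return float(sps.ncf.sf(fcrit, n_predictors, df2, f2 * n))


def required_n_regression(
    f2: float,
    n_predictors: int,
    power: float = 0.80,
    alpha: float = 0.05,
    max_n: int = 10**6,
) -> int:
    """Smallest N at which the regression F test reaches the requested power."""
    if f2 <= 0:
        raise InputError("f2 must be positive")
    if n_predictors < 1:
        raise InputError("n_predictors must be >= 1")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise InputError("power and alpha must lie in (0, 1)")
    # bracket by doubling, then binary-search the monotone power curve
    n = n_predictors + 2
    while regression_power(f2, n_predictors, n, alpha) < power:
        n *= 2
        if n > max_n:
            raise UnreachablePowerError(
                f"power {power} unreachable within N <= {max_n}"
            )
    lo = max(n_predictors + 2, n // 2)
    hi = n
    while lo < hi:
        mid = (lo + hi) // 2
        if regression_power(f2, n_predictors, mid, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    # the power curve is monotone in n for all practical settings; this walk
    # guards against tiny non-monotonicities at very small df
    while lo > n_predictors + 2 and regression_power(f2, n_predictors, lo - 1, alpha) >= power:
        lo -= 1
    return int(lo)
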