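"""Tests of the behavioral-statistics layer: signal detection, contrasts,
correlations, the flanker ratio, and power analysis."""

import numpy as np
import pytest
from scipy import stats as sps

from gazehmm.exceptions import (
    DegenerateVarianceError,
    InputError,
    UnreachablePowerError,
)
from gazehmm.stats import (
    ResponseCounts,
    correlation,
    dprime,
    flanker_effect,
    paired_contrast,
    regression_power,
    required_n_regression,
    rm_anova_2x2,
)


class TestDprime:
    def test_chance_performance_is_zero(self):
        perf = dprime(ResponseCounts(80, 40, 80, 40))
        assert perf.dprime == pytest.approx(0.0, abs=1e-12)
        assert perf.criterion == pytest.approx(0.0, abs=1e-12)

    def test_standard_quantile_oracle(self):
        # z(0.75) - z(0.25), frozen from the normal quantile function
        perf = dprime(ResponseCounts(80, 60, 80, 20))
        assert perf.dprime == pytest.approx(1.3490, abs=5e-5)

    def test_half_count_correction_at_ceiling(self):
        # z(159/160) - z(1/160), finite by construction
        perf = dprime(ResponseCounts(80, 80, 80, 0))
        assert perf.dprime == pytest.approx(4.9954, abs=5e-5)

    def test_no_correction_raises_at_extremes(self):
        with pytest.raises(DegenerateVarianceError):
            dprime(ResponseCounts(80, 80, 80, 10), correction="none")

    def test_antisymmetry_and_monotonicity(self):
        a = dprime(ResponseCounts(50, 35, 50, 15)).dprime
        b = dprime(ResponseCounts(50, 15, 50, 35)).dprime
        assert a == pytest.approx(-b, abs=1e-12)
        prev = -np.inf
        for hits in range(5, 50, 5):
            d = dprime(ResponseCounts(50, hits, 50, 10)).dprime
            assert d > prev
            prev = d

    def test_count_bounds_enforced(self):
        with pytest.raises(InputError):
            ResponseCounts(10, 11, 10, 0)


class TestPairedContrast:
    def test_identical_vectors(self):
        r = paired_contrast([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert r.statistic == 0.0 and r.effect_size == 0.0

    def test_hand_computed_example(self):
        # differences [1,2,3,2,2]: t = 2/(0.70711/sqrt(5)), d = 2/0.70711
        r = paired_contrast([1.0, 2, 3, 2, 2], [0.0] * 5)
        assert r.statistic == pytest.approx(6.3246, abs=5e-5)
        assert r.df == (4,)
        assert r.effect_size == pytest.approx(2.8284, abs=5e-5)
        assert r.effect_ci[0] < r.effect_size < r.effect_ci[1]

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0.3, 1, 30), rng.normal(0, 1, 30)
        r = paired_contrast(x, y)
        ref = sps.ttest_rel(x, y)
        assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0.5, 1, 20), rng.normal(0, 1, 20)
        r1, r2 = paired_contrast(x, y), paired_contrast(y, x)
        assert r1.statistic == pytest.approx(-r2.statistic, abs=1e-12)
        assert r1.effect_size == pytest.approx(-r2.effect_size, abs=1e-12)

    def test_constant_nonzero_difference_raises(self):
        with pytest.raises(DegenerateVarianceError):
            paired_contrast([2.0, 3, 4], [1.0, 2, 3])

    def test_type_one_error_calibration(self):
        """Under a true null the rejection rate at alpha=.05 stays nominal."""
        rng = np.random.default_rng(7)
        n, reps = 25, 2000
        x = rng.normal(size=(reps, n))
        t = x.mean(1) / (x.std(1, ddof=1) / np.sqrt(n))
        crit = sps.t.ppf(0.975, n - 1)
        rate = np.mean(np.abs(t) > crit)
        assert abs(rate - 0.05) < 0.015


class TestRmAnova2x2:
    def test_flat_cells_all_zero(self):
        cells = np.tile([2.0, 2.0, 2.0, 2.0], (10, 1))
        effects = rm_anova_2x2(cells)
        assert all(e.statistic == 0.0 for e in effects.values())

    def test_f_equals_t_squared(self):
        rng = np.random.default_rng(8)
        cells = rng.normal(size=(40, 4)) + np.array([0.0, 0.3, 0.1, 0.5])
        effects = rm_anova_2x2(cells)
        uu, um, mu, mm = cells.T
        checks = {
            "learning_mask": paired_contrast((mu + mm) / 2, (uu + um) / 2),
            "recognition_mask": paired_contrast((um + mm) / 2, (uu + mu) / 2),
            "interaction": paired_contrast(mm - mu, um - uu),
        }
        for name, t_res in checks.items():
            f_res = effects[name]
            assert f_res.statistic == pytest.approx(t_res.statistic**2, rel=1e-12)
            assert 0 <= f_res.effect_size <= 1
            assert f_res.effect_ci[0] <= f_res.effect_size + 1e-12
            assert f_res.effect_size <= f_res.effect_ci[1] + 1e-12

    def test_missing_cells_rejected(self):
        cells = np.full((5, 4), 1.0)
        cells[2, 1] = np.nan
        with pytest.raises(InputError):
            rm_anova_2x2(cells)

    def test_planted_effect_power_matches_analytic(self):
        """Rejection rate of a planted main effect tracks closed-form
        paired-t power within 5 points (the two are the same test)."""
        delta, sd, n, reps, alpha = 0.5, 1.0, 88, 200, 0.05
        # difference scores average two cells, halving the noise variance
        eff_sd = sd / np.sqrt(2)
        ncp = delta / (eff_sd / np.sqrt(n))
        crit = sps.f.ppf(1 - alpha, 1, n - 1)
        analytic = sps.ncf.sf(crit, 1, n - 1, ncp**2)
        rng = np.random.default_rng(9)
        rejections = 0
        for _ in range(reps):
            cells = rng.normal(size=(n, 4)) * sd
            cells[:, 2] += delta
            cells[:, 3] += delta
            res = rm_anova_2x2(cells)["learning_mask"]
            rejections += res.p_value < alpha
        assert abs(rejections / reps - analytic) < 0.05


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r = correlation(x, 2 * x + 1)
        assert r.r == pytest.approx(1.0)
        assert r.df == 8

    def test_partial_removes_shared_covariate(self):
        rng = np.random.default_rng(10)
        z = rng.normal(size=200)
        x = 2.0 * z + rng.normal(scale=1e-6, size=200)
        y = -1.5 * z + rng.normal(scale=1e-6, size=200)
        r = correlation(x, y, covariates=z)
        assert abs(r.r) < 0.2  # residuals are numerical noise
        assert r.df == 197  # n - 2 - one covariate

    def test_empty_covariates_equal_pearson(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=50), rng.normal(size=50)
        plain = correlation(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert plain.r == pytest.approx(ref_r, abs=1e-12)
        assert plain.p_value == pytest.approx(ref_p, abs=1e-10)

    def test_partial_matches_pingouin(self):
        """Residual-method partial correlation against an independent package."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(12)
        z = rng.normal(size=(120, 2))
        x = 0.4 * z[:, 0] + rng.normal(size=120)
        y = 0.3 * z[:, 0] - 0.2 * z[:, 1] + 0.3 * x + rng.normal(size=120)
        df = pd.DataFrame({"x": x, "y": y, "z1": z[:, 0], "z2": z[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        mine = correlation(x, y, covariates=z)
        assert mine.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        pcol = "p_val" if "p_val" in ref.columns else "p-unc"
        assert mine.p_value == pytest.approx(float(ref[pcol].iloc[0]), abs=1e-8)

    def test_planted_partial_in_fisher_band(self):
        """Recovered partial correlation lies in the analytic sampling band."""
        rho, n = 0.3, 500
        rng = np.random.default_rng(13)
        z = rng.normal(size=n)
        ex = rng.normal(size=n)
        ey = rng.normal(size=n)
        x = 0.5 * z + ex
        y = 0.5 * z + rho * ex + np.sqrt(1 - rho**2) * ey
        est = correlation(x, y, covariates=z)
        zr = np.arctanh(est.r)
        z0 = np.arctanh(rho)
        se = 1 / np.sqrt(n - 3 - 1)
        assert abs(zr - z0) < 1.96 * se * 1.5

    def test_constant_vector_raises(self):
        with pytest.raises(DegenerateVarianceError):
            correlation(np.ones(10), np.arange(10.0))


class TestFlankerEffect:
    @pytest.mark.parametrize("i,c,expected", [
        (500.0, 500.0, 0.0),
        (600.0, 400.0, 0.2),
    ])
    def test_values(self, i, c, expected):
        assert flanker_effect(i, c) == pytest.approx(expected)

    def test_antisymmetry_and_domain(self):
        assert flanker_effect(700, 300) == pytest.approx(-flanker_effect(300, 700))
        with pytest.raises(InputError):
            flanker_effect(-1.0, 500.0)


class TestRequiredN:
    def test_medium_effect_four_predictors(self):
        """The classic regression power computation: f2=.15, 4 predictors,
        80% power at alpha .05 requires N=85."""
        assert required_n_regression(0.15, 4, 0.80, 0.05) == 85

    def test_larger_effect_smaller_n(self):
        # frozen from the same noncentral-F scan run independently
        n = required_n_regression(0.35, 4, 0.80, 0.05)
        assert n == 40
        assert n < 85

    def test_monotone_in_effect_size(self):
        prev = np.inf
        for f2 in (0.05, 0.10, 0.20, 0.40):
            n = required_n_regression(f2, 4, 0.80, 0.05)
            assert n <= prev
            prev = n

    def test_returned_n_is_minimal(self):
        n = required_n_regression(0.15, 4, 0.80, 0.05)
        assert regression_power(0.15, 4, n) >= 0.80
        assert regression_power(0.15, 4, n - 1) < 0.80

    def test_unreachable_power_raises(self):
        with pytest.raises(UnreachablePowerError):
            required_n_regression(1e-9, 4, 0.999, 0.001, max_n=10_000)
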