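"""MLE fitting, the Anderson-Darling score and family selection."""

import math
import warnings

import numpy as np
import pytest
from scipy import stats

from fluorisk.fitting import (
    FAMILIES,
    anderson_darling_statistic,
    fit_mle,
    family_frozen,
    normality_test,
    select_distribution,
)

TRUE_PARAMS = {
    "normal": {"loc": 10.0, "scale": 2.0},
    "lognormal": {"meanlog": -3.0, "sdlog": 0.5},
    "logistic": {"loc": 0.02, "scale": 0.005},
    "gumbel_max": {"loc": 10.0, "scale": 2.0},
    "weibull": {"shape": 1.5, "scale": 0.07},
}


def draw(family, params, n, seed):
    rng = np.random.default_rng(seed)
    return np.asarray(family_frozen(family, params).ppf(rng.uniform(size=n)))


class TestFitMle:
    def test_normal_closed_form(self):
        fit = fit_mle([1, 2, 3, 4, 5], "normal")
        assert fit.params["loc"] == 3.0
        assert fit.params["scale"] == pytest.approx(math.sqrt(2), rel=1e-12)
        assert fit.converged

    def test_lognormal_closed_form_is_moments_of_logs(self):
        x = np.exp([0.0, 1.0, 2.0])
        fit = fit_mle(x, "lognormal")
        assert fit.params["meanlog"] == pytest.approx(1.0, rel=1e-12)
        assert fit.params["sdlog"] == pytest.approx(np.std([0, 1, 2]), rel=1e-12)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_parameter_recovery_at_n5000(self, family):
        x = draw(family, TRUE_PARAMS[family], 5000, seed=7)
        fit = fit_mle(x, family)
        assert fit.converged
        for name, true in TRUE_PARAMS[family].items():
            assert fit.params[name] == pytest.approx(true, rel=0.05), (family, name)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            fit_mle([2.0, 2.0, 2.0], "normal")

    def test_zeros_excluded_for_positive_support_with_warning(self):
        x = np.concatenate([[0.0, 0.0], draw("weibull", TRUE_PARAMS["weibull"], 100, 3)])
        with pytest.warns(UserWarning, match="zero"):
            fit = fit_mle(x, "weibull")
        assert fit.n == 100

    def test_negative_samples_rejected_for_positive_support(self):
        with pytest.raises(ValueError, match="positive"):
            fit_mle([-1.0, 1.0, 2.0], "lognormal")

    def test_loglik_matches_direct_evaluation(self):
        x = draw("gumbel_max", TRUE_PARAMS["gumbel_max"], 200, 11)
        fit = fit_mle(x, "gumbel_max")
        direct = float(np.sum(fit.frozen.logpdf(x)))
        assert fit.loglik == pytest.approx(direct, rel=1e-12)


class TestAndersonDarling:
    def test_hand_value_on_three_point_uniform(self):
        a2 = anderson_darling_statistic([0.25, 0.5, 0.75], lambda x: x)
        assert a2 == pytest.approx(0.26943, abs=5e-6)

    def test_depends_only_on_probability_transform(self):
        # samples at the exact (i-0.5)/n quantiles of any family give the
        # same statistic, a pure functional of the CDF values
        n = 10
        q = (np.arange(1, n + 1) - 0.5) / n
        values = []
        for family, params in TRUE_PARAMS.items():
            frozen = family_frozen(family, params)
            values.append(anderson_darling_statistic(frozen.ppf(q), frozen.cdf))
        assert np.ptp(values) < 1e-9

    def test_tail_outlier_increases_statistic(self):
        x = np.linspace(0.1, 0.9, 10)
        base = anderson_darling_statistic(x, lambda v: np.clip(v, 0, 1))
        shifted = x.copy()
        shifted[-1] = 0.999999
        worse = anderson_darling_statistic(shifted, lambda v: np.clip(v, 0, 1))
        assert worse > base

    def test_boundary_cdf_values_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            a2 = anderson_darling_statistic([0.0, 0.5, 1.0], lambda x: x)
        assert np.isfinite(a2)

    def test_affine_invariance_for_location_scale_family(self):
        x = draw("normal", TRUE_PARAMS["normal"], 50, 5)
        fit = fit_mle(x, "normal")
        y = 3.0 * x - 7.0
        fit_y = fit_mle(y, "normal")
        assert fit_y.ad_stat == pytest.approx(fit.ad_stat, rel=1e-9)

    def test_matches_scipy_anderson_for_fitted_normal(self):
        # independent oracle: scipy's Anderson-Darling normality statistic
        x = draw("normal", TRUE_PARAMS["normal"], 80, 21)
        ours = fit_mle(x, "normal").ad_stat
        # scipy fits loc/scale with mean and the ddof=1 SD; mirror that CDF
        loc, scale = np.mean(x), np.std(x, ddof=1)
        ours_ddof1 = anderson_darling_statistic(
            x, stats.norm(loc, scale).cdf
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            theirs = stats.anderson(x, dist="norm").statistic
        assert ours_ddof1 == pytest.approx(theirs, rel=1e-9)
        assert ours == pytest.approx(theirs, rel=0.05)

    def test_pit_mean_stable_across_generating_families(self):
        # A^2 against the true CDF is distribution-free; its mean at n=100
        # is near 1 for every family (E[A^2] = 1 asymptotically)
        means = []
        for family, params in TRUE_PARAMS.items():
            frozen = family_frozen(family, params)
            vals = [
                anderson_darling_statistic(
                    draw(family, params, 100, seed), frozen.cdf
                )
                for seed in range(40)
            ]
            means.append(np.mean(vals))
        assert np.ptp(means) < 0.5
        assert all(0.6 < m < 1.5 for m in means)


class TestNormalityScreen:
    def test_null_rejection_rate_near_nominal(self):
        hits = sum(
            normality_test(np.random.default_rng(s).normal(size=500)).p_value > 0.05
            for s in range(100)
        )
        assert hits >= 90

    def test_power_against_strong_skew(self):
        hits = sum(
            normality_test(
                np.random.default_rng(s).exponential(size=500)
            ).p_value < 0.05
            for s in range(100)
        )
        assert hits >= 95

    def test_symmetric_three_point_sample_near_linear(self):
        report = normality_test([-1.0, 0.0, 1.0])
        assert report.statistic > 0.9
        assert "Shapiro" in report.method

    def test_sample_size_bounds_enforced(self):
        with pytest.raises(ValueError, match="n="):
            normality_test([1.0, 2.0])


class TestSelectDistribution:
    def test_weibull_selection_consistency(self):
        hits = 0
        for seed in range(100):
            x = draw("weibull", {"shape": 1.5, "scale": 0.07}, 1000, seed)
            if select_distribution(x, FAMILIES)[0].family == "weibull":
                hits += 1
        assert hits >= 80

    def test_gumbel_beats_normal(self):
        hits = 0
        for seed in range(100):
            x = draw("gumbel_max", {"loc": 10, "scale": 2}, 1000, seed)
            ranked = select_distribution(x, ("normal", "gumbel_max"))
            if ranked[0].family == "gumbel_max":
                hits += 1
        assert hits >= 90

    def test_single_candidate_trivially_first(self):
        x = draw("normal", TRUE_PARAMS["normal"], 100, 2)
        ranked = select_distribution(x, ("normal",))
        assert [f.family for f in ranked] == ["normal"]

    def test_ranking_ascends_in_ad(self):
        x = draw("logistic", TRUE_PARAMS["logistic"], 500, 9)
        ranked = select_distribution(x, FAMILIES)
        ads = [f.ad_stat for f in ranked]
        assert ads == sorted(ads)

    def test_all_candidates_failing_raises_with_reasons(self):
        with pytest.raises(ValueError, match="positive"):
            select_distribution([-3.0, -2.0, -1.0], ("lognormal", "weibull"))
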