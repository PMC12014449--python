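"""Seeded Monte Carlo propagation: determinism, degeneracy, convergence."""

import numpy as np
import pytest

from fluorisk.exposure import average_daily_dose, exposure_parameters, hazard_quotient
from fluorisk.fitting import FittedDistribution
from fluorisk.montecarlo import (
    ScenarioSpec,
    SimulationConfig,
    percentile,
    point_mass,
    sample_family,
    scenario_rng,
    simulate_hi,
    simulate_hq,
)


def normal_dist(loc, scale):
    return FittedDistribution(
        family="normal", params={"loc": loc, "scale": scale},
        n=3, loglik=float("nan"), ad_stat=float("nan"), converged=True,
    )


def scenario(food="corn", day=30, group="children", c=(308.24, 0.0), ir=(0.010, 0.0)):
    return ScenarioSpec(
        food=food, roast_day=day, group=group,
        c_dist=normal_dist(*c), ir_dist=normal_dist(*ir),
        params=exposure_parameters(group, food),
    )


class TestSampleFamily:
    def test_large_sample_mean_near_location(self):
        rng = np.random.default_rng(0)
        x = sample_family(normal_dist(0.0, 1.0), 100_000, rng)
        assert abs(x.mean()) < 0.02  # 3 sigma / sqrt(n) bound

    def test_zero_scale_is_point_mass(self):
        rng = np.random.default_rng(0)
        x = sample_family(normal_dist(5.0, 0.0), 100, rng)
        assert np.all(x == 5.0)

    def test_same_seed_identical_draws(self):
        a = sample_family(normal_dist(0, 1), 1000, np.random.default_rng(42))
        b = sample_family(normal_dist(0, 1), 1000, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            sample_family(normal_dist(0, -1.0), 10, np.random.default_rng(0))


class TestPercentile:
    def test_median_of_odd_vector(self):
        assert percentile([1, 2, 3, 4, 5], 0.5) == 3.0

    def test_linear_interpolation_convention(self):
        assert percentile([1, 2, 3, 4], 0.05) == pytest.approx(1.15, rel=1e-12)

    def test_monotone_in_q(self, rng):
        x = rng.normal(size=200)
        assert percentile(x, 0.95) >= percentile(x, 0.05)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            percentile([], 0.5)


class TestSimulateHq:
    def test_degenerate_inputs_reproduce_point_estimate(self):
        config = SimulationConfig(seed=1, n_iter=100)
        s = scenario()
        out = simulate_hq(s, config)
        expected = hazard_quotient(
            average_daily_dose(308.24, s.params), s.params.rfd
        )
        assert out.mean == pytest.approx(expected, abs=1e-12)
        assert out.p05 == pytest.approx(expected, abs=1e-12)
        assert out.p95 == pytest.approx(expected, abs=1e-12)
        assert round(out.mean, 2) == 1.98

    def test_mean_matches_analytic_expectation(self):
        config = SimulationConfig(seed=3, n_iter=100_000)
        s = scenario(c=(100.0, 10.0), ir=(0.02, 0.0))
        out = simulate_hq(s, config)
        analytic = 100.0 * 0.02 / (25.9 * 0.06)
        assert out.mean == pytest.approx(analytic, rel=0.01)

    def test_negative_lower_tail_without_truncation(self):
        s = scenario(c=(50.0, 50.0), ir=(0.02, 0.0))
        out = simulate_hq(s, SimulationConfig(seed=5, n_iter=20_000))
        # Pr(C < 0) ~ 0.159 at mu/sigma = 1, so the 5th percentile is negative
        assert out.p05 < 0

    def test_truncation_raises_mean_and_p05(self):
        s = scenario(c=(50.0, 50.0), ir=(0.02, 0.0))
        free = simulate_hq(s, SimulationConfig(seed=5, n_iter=20_000))
        trunc = simulate_hq(
            s, SimulationConfig(seed=5, n_iter=20_000, truncate_negative=True)
        )
        assert trunc.mean >= free.mean
        assert trunc.p05 >= free.p05
        assert trunc.p05 >= 0

    def test_bit_identical_summaries_for_same_config(self):
        s = scenario(c=(100.0, 20.0), ir=(0.02, 0.005))
        a = simulate_hq(s, SimulationConfig(seed=9, n_iter=5000))
        b = simulate_hq(s, SimulationConfig(seed=9, n_iter=5000))
        assert (a.mean, a.p05, a.p95, a.prob_hq_above_1) == (
            b.mean, b.p05, b.p95, b.prob_hq_above_1,
        )

    def test_small_iteration_count_warns_on_tails(self):
        with pytest.warns(UserWarning, match="percentile"):
            simulate_hq(scenario(), SimulationConfig(seed=1, n_iter=10))

    def test_convergence_rate_is_square_root(self):
        # |MC mean - analytic| should shrink as O(1/sqrt(n)): log-log slope
        # of the seed-averaged absolute error vs n close to -0.5
        s = scenario(c=(100.0, 30.0), ir=(0.02, 0.004))
        analytic = 100.0 * 0.02 / (25.9 * 0.06)
        ns = [100, 1000, 10_000, 100_000]
        errors = []
        for n in ns:
            errs = [
                abs(simulate_hq(s, SimulationConfig(seed=seed, n_iter=n)).mean
                    - analytic)
                for seed in range(20)
            ]
            errors.append(np.mean(errs))
        slope = np.polyfit(np.log(ns), np.log(errors), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)


class TestSimulateHi:
    def test_four_identical_degenerate_quarters_sum_to_one(self):
        foods = ["corn", "chili", "pork", "tofu"]
        scenarios = []
        for f in foods:
            p = exposure_parameters("children", f)
            # choose the concentration that sets this food's HQ to 0.25
            c = 0.25 * p.rfd * p.bw / p.ir
            scenarios.append(
                ScenarioSpec(f, 0, "children", normal_dist(c, 0.0),
                             normal_dist(p.ir, 0.0), p)
            )
        out = simulate_hi(scenarios, SimulationConfig(seed=2, n_iter=500))
        assert out.mean == pytest.approx(1.0, abs=1e-12)
        assert out.food == "ALL"

    def test_index_mean_is_sum_of_quotient_means(self):
        config = SimulationConfig(seed=7, n_iter=10_000)
        scenarios = [
            scenario("corn", 30, "children", c=(300.0, 60.0), ir=(0.010, 0.002)),
            scenario("pork", 30, "children", c=(140.0, 30.0), ir=(0.033, 0.01)),
        ]
        hi = simulate_hi(scenarios, config)
        hq_sum = sum(simulate_hq(s, config).mean for s in scenarios)
        # identical keyed substreams make the draws shared, so the identity
        # is exact, well within the 3-SE Monte Carlo bound
        assert hi.mean == pytest.approx(hq_sum, rel=1e-12)

    def test_single_scenario_index_equals_quotient(self):
        config = SimulationConfig(seed=4, n_iter=2000)
        s = scenario(c=(100.0, 20.0), ir=(0.02, 0.004))
        hi = simulate_hi([s], config)
        hq = simulate_hq(s, config)
        assert hi.mean == hq.mean
        assert hi.p95 == hq.p95

    def test_mixed_stage_rejected(self):
        with pytest.raises(ValueError, match="roast_day"):
            simulate_hi([scenario(day=0), scenario(food="pork", day=30)],
                        SimulationConfig(seed=1, n_iter=10, percentiles=()))


class TestScenarioStreams:
    def test_streams_keyed_by_identity_not_order(self):
        a = scenario_rng(1, "corn", 30, "children", "conc").uniform(size=5)
        b = scenario_rng(1, "corn", 30, "children", "conc").uniform(size=5)
        other = scenario_rng(1, "pork", 30, "children", "conc").uniform(size=5)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, other)

    def test_adding_a_scenario_does_not_perturb_others(self):
        config = SimulationConfig(seed=11, n_iter=1000)
        s1 = scenario(c=(100.0, 20.0), ir=(0.02, 0.004))
        alone = simulate_hq(s1, config)
        _ = simulate_hq(scenario(food="pork", c=(50.0, 5.0)), config)
        again = simulate_hq(s1, config)
        assert alone.mean == again.mean
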