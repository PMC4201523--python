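"""Bootstrap economics: ICERs, percentile intervals, CEACs, thresholds
and currency conversion."""

import itertools

import numpy as np
import pytest

from rrdcua import (AnalysisError, BootstrapResult, BootstrapSettings,
                    CeacCurve, DomainError, EconParams, bootstrap_cua, ceac,
                    convert_currency, icer, percentile_interval, verdict,
                    wtp_at_probability, wtp_threshold_from_gdp)


class TestIcer:
    @pytest.mark.parametrize("dc,de,expected", [
        (100, 0.5, 200),
        (12_992, 0.40, 32_480),  # ratio of point means
        (0, 0.4, 0),
    ])
    def test_ratio(self, dc, de, expected):
        assert icer(dc, de) == pytest.approx(expected)

    def test_zero_denominator(self):
        with pytest.raises(DomainError):
            icer(100, 0.0)


class TestPercentileInterval:
    def test_constant_vector(self):
        assert percentile_interval([7, 7, 7, 7], 2.5, 97.5) == (7.0, 7.0)

    def test_order_statistic_interpolation(self):
        """Hand calculation: rank (n-1)p/100 with linear interpolation."""
        x = list(range(1, 101))
        lo, hi = percentile_interval(x, 2.5, 97.5)
        # rank 99*0.025 = 2.475 -> between 3rd and 4th order stats (3, 4)
        assert lo == pytest.approx(3 + 0.475)
        # rank 99*0.975 = 96.525 -> between values 97 and 98
        assert hi == pytest.approx(97 + 0.525)

    def test_single_sample(self):
        assert percentile_interval([5], 2.5, 97.5) == (5.0, 5.0)

    def test_empty_input(self):
        with pytest.raises(AnalysisError):
            percentile_interval([], 2.5, 97.5)

    def test_misordered_percentiles(self):
        with pytest.raises(DomainError):
            percentile_interval([1, 2, 3], 97.5, 2.5)


class TestBootstrap:
    def test_degenerate_cohort_has_zero_width_cis(self):
        costs = np.full(10, 10_000.0)
        qalys = np.full(10, 0.5)
        res = bootstrap_cua(costs, qalys, BootstrapSettings(replications=200, seed=1))
        assert np.all(res.delta_cost == 10_000.0)
        assert np.all(res.delta_qaly == 0.5)
        assert np.all(res.icers == 20_000.0)
        assert res.cost_ci == (10_000.0, 10_000.0)
        assert res.qaly_ci == (0.5, 0.5)
        assert res.mean_icer == pytest.approx(20_000.0)

    def test_two_patient_enumeration_oracle(self):
        """All 4 equally likely resamples of {0, 100} give the exact
        distribution of the replicate mean; the bootstrap matches it
        within 3 Monte-Carlo standard errors."""
        costs = np.array([0.0, 100.0])
        means = [np.mean(pick) for pick in itertools.product(costs, repeat=2)]
        mu = np.mean(means)                      # 50
        var = np.mean((np.array(means) - mu) ** 2)   # 1250
        m4 = np.mean((np.array(means) - mu) ** 4)
        B = 10_000
        res = bootstrap_cua(costs, np.ones(2), BootstrapSettings(replications=B, seed=11))
        se_mean = np.sqrt(var / B)
        assert res.delta_cost.mean() == pytest.approx(mu, abs=3 * se_mean)
        se_var = np.sqrt((m4 - var ** 2) / B)
        assert res.delta_cost.var() == pytest.approx(var, abs=3 * se_var)

    def test_deterministic_under_fixed_seed(self, synthetic_cohort_98, life_table):
        from rrdcua import project_cohort
        from rrdcua.qaly import projected_gains
        gains = projected_gains(project_cohort(synthetic_cohort_98, life_table,
                                               EconParams()))
        s = BootstrapSettings(replications=500, seed=99)
        r1 = bootstrap_cua(synthetic_cohort_98.costs(), gains, s)
        r2 = bootstrap_cua(synthetic_cohort_98.costs(), gains, s)
        assert np.array_equal(r1.delta_cost, r2.delta_cost)
        assert np.array_equal(r1.delta_qaly, r2.delta_qaly)
        assert r1.mean_icer == r2.mean_icer

    def test_replicate_means_converge_to_cohort_mean(self, synthetic_cohort_98):
        costs = synthetic_cohort_98.costs()
        B = 10_000
        res = bootstrap_cua(costs, np.ones_like(costs),
                            BootstrapSettings(replications=B, seed=5))
        # grand mean over B replicate means is unbiased for the cohort mean,
        # with Monte-Carlo SE ~ sd / sqrt(n * B)
        agg_se = costs.std(ddof=1) / np.sqrt(len(costs) * B)
        assert res.delta_cost.mean() == pytest.approx(costs.mean(), abs=3 * agg_se)

    def test_near_degenerate_cohort_mean_icer_close_to_ratio(self):
        """On a symmetric low-variance cohort both ICER statistics sit at
        the true ratio within Monte-Carlo tolerance."""
        rng = np.random.default_rng(8)
        costs = 10_000 + rng.normal(0, 10, 200)
        qalys = 0.5 + rng.normal(0, 0.001, 200)
        res = bootstrap_cua(costs, qalys, BootstrapSettings(replications=2000, seed=8))
        assert res.mean_icer == pytest.approx(res.icer_of_means, rel=1e-3)
        assert res.mean_icer == pytest.approx(20_000, rel=1e-2)

    def test_zero_qaly_replicates_excluded_and_counted(self):
        costs = np.array([100.0, 100.0])
        qalys = np.array([0.0, 0.0])
        res = bootstrap_cua(costs, qalys, BootstrapSettings(replications=50, seed=2))
        assert res.n_excluded == 50
        assert np.isnan(res.mean_icer)

    def test_empty_cohort_rejected(self):
        with pytest.raises(AnalysisError):
            bootstrap_cua(np.array([]), np.array([]), BootstrapSettings())

    def test_invalid_settings_rejected(self):
        with pytest.raises(DomainError):
            BootstrapSettings(replications=0)
        with pytest.raises(DomainError):
            BootstrapSettings(ci_lower=97.5, ci_upper=2.5)


def four_replicate_result() -> BootstrapResult:
    """Fixed replicates with ICERs 20k/25k/30k/35k, all positive QALYs."""
    dc = np.array([20_000.0, 25_000.0, 30_000.0, 35_000.0])
    de = np.ones(4)
    return BootstrapResult(
        delta_cost=dc, delta_qaly=de, icers=dc / de,
        mean_cost=float(dc.mean()), cost_ci=(20_000.0, 35_000.0),
        mean_qaly=1.0, qaly_ci=(1.0, 1.0),
        mean_icer=float(dc.mean()), icer_of_means=float(dc.mean()),
        n_excluded=0,
    )


class TestCeac:
    def test_zero_threshold_with_positive_costs(self):
        res = four_replicate_result()
        curve = ceac(res, [1e-9])  # effectively lambda -> 0
        assert curve.probability[0] == 0.0

    def test_probability_one_beyond_max_icer(self):
        res = four_replicate_result()
        curve = ceac(res, [100_000.0])
        assert curve.probability[0] == 1.0

    def test_hand_counted_midpoint(self):
        res = four_replicate_result()
        curve = ceac(res, [27_000.0])
        assert curve.probability[0] == pytest.approx(0.5)

    def test_monotone_when_all_qalys_positive(self, synthetic_cohort_98, life_table):
        from rrdcua import project_cohort
        from rrdcua.qaly import projected_gains
        gains = projected_gains(project_cohort(synthetic_cohort_98, life_table,
                                               EconParams()))
        res = bootstrap_cua(synthetic_cohort_98.costs(), gains,
                            BootstrapSettings(replications=1000, seed=3))
        assert np.all(res.delta_qaly > 0)
        curve = ceac(res, np.arange(1_000.0, 120_000.0, 1_000.0))
        assert np.all(np.diff(curve.probability) >= 0)

    def test_ties_count_as_not_cost_effective(self):
        res = four_replicate_result()
        curve = ceac(res, [20_000.0])  # NMB of the cheapest replicate is exactly 0
        assert curve.probability[0] == 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(AnalysisError):
            ceac(four_replicate_result(), [])

    def test_curve_invariants_enforced(self):
        with pytest.raises(AnalysisError):
            CeacCurve(np.array([2.0, 1.0]), np.array([0.1, 0.2]))
        with pytest.raises(AnalysisError):
            CeacCurve(np.array([1.0, 2.0]), np.array([0.1, 1.2]))


class TestWtp:
    def make_curve(self):
        return CeacCurve(np.array([10_000.0, 20_000.0, 30_000.0]),
                         np.array([0.2, 0.6, 0.95]))

    def test_first_crossing(self):
        assert wtp_at_probability(self.make_curve(), 0.5) == 20_000.0

    def test_higher_target(self):
        assert wtp_at_probability(self.make_curve(), 0.95) == 30_000.0

    def test_unreachable_target(self):
        with pytest.raises(AnalysisError):
            wtp_at_probability(self.make_curve(), 0.99)

    @pytest.mark.parametrize("gdp,mult,expected", [
        (38_354, 3, 115_062),
        (38_354, 1, 38_354),
        (1, 3, 3),
    ])
    def test_gdp_threshold(self, gdp, mult, expected):
        assert wtp_threshold_from_gdp(gdp, mult) == expected

    def test_gdp_threshold_rejects_nonpositive(self):
        with pytest.raises(DomainError):
            wtp_threshold_from_gdp(-1, 3)


class TestCurrencyAndVerdict:
    @pytest.mark.parametrize("cny,usd", [
        (115_062, 18_293),
        (33_186, 5_276),
        (71_240, 11_326),
        (0, 0),
    ])
    def test_round_half_up_conversion(self, cny, usd):
        assert convert_currency(cny, 6.29) == usd

    def test_half_up_at_exact_half(self):
        assert convert_currency(2.5, 1.0) == 3

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(DomainError):
            convert_currency(100, 0.0)

    def test_verdict_bands(self):
        p = EconParams()  # GDP 38,354; threshold 115,062
        assert verdict(20_000, p) == "highly_cost_effective"
        assert verdict(50_000, p) == "cost_effective"
        assert verdict(120_000, p) == "not_cost_effective"
        assert verdict(float("nan"), p) == "undetermined"
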