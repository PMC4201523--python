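"""Discounted lifetime QALY projection: annuity factors, first-year
conventions, life-table lookups and cohort projection."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from rrdcua import (Cohort, DomainError, EconParams, LifeTableError,
                    annuity_factor, lifetime_qaly_gain, project_cohort,
                    remaining_life_expectancy)
from conftest import make_patient


def annuity_brute_force(n_years: float, rate: float) -> float:
    """Independent year-by-year oracle for the annuity factor."""
    total, t = 0.0, 1
    remaining = n_years
    while remaining > 0:
        frac = min(1.0, remaining)
        total += frac / (1.0 + rate) ** t
        remaining -= 1.0
        t += 1
    return total


class TestAnnuityFactor:
    @pytest.mark.parametrize("n,r,expected", [
        (5, 0.0, 5.0),
        (1, 0.03, 1 / 1.03),
        (10, 0.03, (1 - 1.03 ** -10) / 0.03),           # = 8.530203...
        (2.5, 0.03, 1.03 ** -1 + 1.03 ** -2 + 0.5 * 1.03 ** -3),
        (0, 0.03, 0.0),
    ])
    def test_reference_values(self, n, r, expected):
        assert annuity_factor(n, r) == pytest.approx(expected, abs=1e-12)

    def test_matches_closed_form_on_grid(self):
        for r in np.arange(0.01, 0.105, 0.01):
            for n in range(1, 31):
                closed = (1 - (1 + r) ** -n) / r
                assert annuity_factor(n, r) == pytest.approx(closed, abs=1e-12)

    @hsettings(derandomize=True, max_examples=200)
    @given(n=st.floats(0, 60), r=st.floats(0, 0.2))
    def test_matches_brute_force_sum(self, n, r):
        assert annuity_factor(n, r) == pytest.approx(annuity_brute_force(n, r), abs=1e-9)

    def test_vectorized_matches_scalar(self):
        ns = np.array([0.0, 1.0, 2.5, 10.0])
        out = annuity_factor(ns, 0.03)
        assert out == pytest.approx([annuity_factor(float(n), 0.03) for n in ns])

    @pytest.mark.parametrize("n,r", [(-1, 0.03), (5, -0.01)])
    def test_rejects_negative_inputs(self, n, r):
        with pytest.raises(DomainError):
            annuity_factor(n, r)


class TestLifetimeQalyGain:
    def test_zero_gain_gives_zero(self, params):
        for L in (1.0, 8.6, 25.0):
            assert lifetime_qaly_gain(0.0, L, params) == 0.0

    def test_ramp_year_only(self, params):
        assert lifetime_qaly_gain(0.1, 1.0, params) == pytest.approx(0.05)

    def test_undiscounted_sum(self):
        p = EconParams(discount_rate=0.0)
        assert lifetime_qaly_gain(0.07, 11.0, p) == pytest.approx(0.07 * 10.5)

    def test_matches_year_by_year_oracle(self, params):
        expected = 0.07 * 0.5 + 0.07 * annuity_brute_force(7.0, 0.03)
        assert lifetime_qaly_gain(0.07, 8.0, params) == pytest.approx(expected, abs=1e-12)

    def test_full_gain_convention(self):
        p = EconParams(first_year_model="full_gain")
        assert lifetime_qaly_gain(0.07, 8.0, p) == pytest.approx(
            0.07 * annuity_brute_force(8.0, 0.03), abs=1e-12)

    @hsettings(derandomize=True, max_examples=100)
    @given(gain=st.floats(0.001, 0.3), L=st.floats(0.5, 30))
    def test_monotone_non_increasing_in_discount_rate(self, gain, L):
        vals = [lifetime_qaly_gain(gain, L, EconParams(discount_rate=r))
                for r in (0.0, 0.03, 0.05)]
        assert vals[0] >= vals[1] >= vals[2]

    @hsettings(derandomize=True, max_examples=100)
    @given(gain=st.floats(-0.5, 0.5), L=st.floats(0.5, 30), r=st.floats(0, 0.1))
    def test_linear_in_gain_and_bounded(self, gain, L, r):
        p = EconParams(discount_rate=r)
        g1 = lifetime_qaly_gain(gain, L, p)
        g2 = lifetime_qaly_gain(2 * gain, L, p)
        assert g2 == pytest.approx(2 * g1, abs=1e-12)
        assert abs(g1) <= abs(gain) * L + 1e-12
        assert np.sign(g1) == np.sign(gain) or gain == 0

    def test_rejects_nonpositive_expectancy(self, params):
        with pytest.raises(DomainError):
            lifetime_qaly_gain(0.07, 0.0, params)


class TestRemainingLifeExpectancy:
    def test_exact_row(self, life_table):
        assert remaining_life_expectancy(80, "male", life_table) == 7.5

    def test_linear_interpolation_midpoint(self, life_table):
        assert remaining_life_expectancy(75, "female", life_table) == pytest.approx(12.0)

    def test_interpolated_value_between_brackets(self, life_table):
        for age in (71, 74.5, 78, 83, 89.9):
            v = remaining_life_expectancy(age, "male", life_table)
            lo_age = 70 if age < 80 else 80
            hi_age = 80 if age < 80 else 90
            hi_v = remaining_life_expectancy(lo_age, "male", life_table)
            lo_v = remaining_life_expectancy(hi_age, "male", life_table)
            assert lo_v <= v <= hi_v

    def test_clamps_above_table_maximum(self, life_table):
        assert remaining_life_expectancy(95, "male", life_table) == 4.0

    def test_age_below_range_errors(self, life_table):
        with pytest.raises(LifeTableError):
            remaining_life_expectancy(65, "male", life_table)

    def test_unknown_sex_errors(self, life_table):
        with pytest.raises(LifeTableError):
            remaining_life_expectancy(75, "unknown", life_table)


class TestProjectCohort:
    def test_no_gain_projects_to_zero(self, life_table, params):
        cohort = Cohort([make_patient(f"p{i}", utility_pre=0.8, utility_1y=0.8)
                         for i in range(4)])
        projections = project_cohort(cohort, life_table, params)
        assert all(p.discounted_qalys_gained == 0.0 for p in projections)

    def test_single_patient_matches_hand_sum(self, life_table, params):
        # 78-year-old male: expectancy interpolates to 13.0 + 0.8*(7.5-13.0) = 8.6
        cohort = Cohort([make_patient(age=78, sex="male",
                                      utility_pre=0.77, utility_1y=0.84)])
        (proj,) = project_cohort(cohort, life_table, params)
        assert proj.life_expectancy == pytest.approx(8.6)
        gain = 0.84 - 0.77
        expected = gain * 0.5 + gain * annuity_brute_force(7.6, 0.03)
        assert proj.discounted_qalys_gained == pytest.approx(expected, abs=1e-12)

    def test_discounting_reduces_every_projection(self, life_table, synthetic_cohort_98):
        g0 = project_cohort(synthetic_cohort_98, life_table, EconParams(discount_rate=0.0))
        g5 = project_cohort(synthetic_cohort_98, life_table, EconParams(discount_rate=0.05))
        for a, b in zip(g0, g5):
            if a.gain > 0:
                assert a.discounted_qalys_gained >= b.discounted_qalys_gained

    def test_error_names_patient(self, life_table, params):
        cohort = Cohort([make_patient("young", age=64)])
        with pytest.raises(LifeTableError, match="young"):
            project_cohort(cohort, life_table, params)
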