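import math

import pytest
from hypothesis import given, strategies as st

from bphbia import (
    PopulationConfig,
    ValidationError,
    annual_to_cycle_prob,
    eligible_population,
    entrants_for_cycle,
    incidence_rate_per_1000py,
)


class TestEligiblePopulation:
    @pytest.mark.parametrize("census,prev,ms,expected", [
        (1_724_867, 0.30, 0.63, 326_000),   # census x prevalence x severity mix
        (123_456, 0.0, 0.5, 0),
        (100_000, 0.20, 0.50, 10_000),
    ])
    def test_examples(self, census, prev, ms, expected):
        assert eligible_population(census, prev, ms) == expected

    @pytest.mark.parametrize("census,prev,ms", [
        (-1, 0.3, 0.63), (1000, 1.5, 0.63), (1000, 0.3, -0.1)])
    def test_rejects_out_of_range(self, census, prev, ms):
        with pytest.raises(ValidationError):
            eligible_population(census, prev, ms)

    @given(census=st.integers(0, 10_000_000),
           prev=st.floats(0.0, 1.0), ms=st.floats(0.0, 1.0))
    def test_linear_up_to_report_rounding(self, census, prev, ms):
        # linear in each argument; the nearest-integer report rounding can
        # shift each evaluation by at most half a person
        doubled = eligible_population(2 * census, prev, ms)
        single = eligible_population(census, prev, ms)
        assert abs(doubled - 2 * single) <= 1


class TestIncidence:
    def test_reported_rate(self):
        assert round(incidence_rate_per_1000py(2_090, 110_321), 2) == 18.94

    @pytest.mark.parametrize("events,py,expected", [
        (0, 110_321, 0.0), (1, 1_000, 1.0)])
    def test_trivial(self, events, py, expected):
        assert incidence_rate_per_1000py(events, py) == expected

    def test_rejects_nonpositive_person_years(self):
        with pytest.raises(ValidationError):
            incidence_rate_per_1000py(10, 0)


class TestAnnualToCycle:
    def test_boundaries(self):
        assert annual_to_cycle_prob(0.0) == 0.0
        assert annual_to_cycle_prob(1.0) == 1.0

    def test_against_daily_compounding_oracle(self):
        # independent oracle: compound a per-day hazard over a quarter
        p_annual = 0.2
        daily = 1.0 - (1.0 - p_annual) ** (1.0 / 365.0)
        quarterly = 1.0 - (1.0 - daily) ** (365.0 / 4.0)
        assert annual_to_cycle_prob(0.2) == pytest.approx(quarterly, abs=1e-12)
        assert annual_to_cycle_prob(0.2) == pytest.approx(0.054258, abs=1e-6)

    @given(p=st.floats(0.0, 1.0))
    def test_four_cycle_complement_product_recovers_annual(self, p):
        pc = annual_to_cycle_prob(p, 4)
        assert 1.0 - (1.0 - pc) ** 4 == pytest.approx(p, abs=1e-12)

    @given(p1=st.floats(0.0, 1.0), p2=st.floats(0.0, 1.0))
    def test_monotone(self, p1, p2):
        lo, hi = sorted((p1, p2))
        assert annual_to_cycle_prob(lo) <= annual_to_cycle_prob(hi)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            annual_to_cycle_prob(1.2)


class TestEntrants:
    def test_no_entrants_in_year_one(self):
        assert entrants_for_cycle(1_724_867, 18.94, 0.25, current_year=1) == 0.0

    def test_year_two_flow(self):
        got = entrants_for_cycle(1_724_867, 18.94, 0.25, current_year=2)
        assert got == pytest.approx(8_167.2, abs=0.5)

    def test_zero_population(self):
        assert entrants_for_cycle(0, 18.94, 0.25, current_year=3) == 0.0

    @given(year=st.integers(2, 4), pop=st.floats(0, 1e7), rate=st.floats(0, 100))
    def test_direct_arithmetic(self, year, pop, rate):
        assert entrants_for_cycle(pop, rate, 0.25, year) == \
            pytest.approx(pop * rate / 1000 * 0.25)

    def test_rejects_bad_year(self):
        with pytest.raises(ValidationError):
            entrants_for_cycle(1000, 18.94, 0.25, current_year=5)


class TestPopulationConfig:
    def test_defaults_reproduce_reported_cohort(self):
        cfg = PopulationConfig()
        assert round(cfg.eligible) == 326_000
        assert round(cfg.incidence_rate, 2) == 18.94

    @pytest.mark.parametrize("kw", [
        {"prevalence": 1.5},
        {"initial_split": (0.5, 0.5, 0.5)},
        {"census_males_50plus": 0},
        {"incidence_person_years": -1},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValidationError):
            PopulationConfig(**kw)

    def test_split_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            PopulationConfig(initial_split=(0.07, 0.63, 0.31))
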