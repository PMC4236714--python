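import numpy as np
import pytest
from hypothesis import given, strategies as st

from bphbia import (
    PRIVATE_COSTS,
    PUBLIC_COSTS,
    DrugPrices,
    HealthState,
    PathwayParams,
    ResourceProfile,
    aur_cost,
    drug_cycle_cost,
    state_cycle_cost,
    surgery_cost,
)
from bphbia.costing import cycle_component_costs
from bphbia.states import CycleEvents

PROFILE = ResourceProfile()


class TestStateCycleCost:
    def test_severe_subsequent_public(self):
        # (2.78 urologist visits x 10.00 + expected cystoscopy
        #  0.39 x 0.07 x 4.05) per year, billed quarterly
        got = state_cycle_cost(HealthState.SEVERE, False, PROFILE, PUBLIC_COSTS)
        assert got == pytest.approx((2.78 * 10.00 + 0.39 * 0.07 * 4.05) / 4, abs=1e-3)
        assert got == pytest.approx(6.9777, abs=1e-3)

    def test_moderate_subsequent_public(self):
        got = state_cycle_cost(HealthState.MODERATE, False, PROFILE, PUBLIC_COSTS)
        assert got == pytest.approx((2.39 * 10.00 + 2 * PUBLIC_COSTS.gp_visit) / 4)

    def test_zero_profile_costs_nothing(self):
        empty = ResourceProfile(
            urologist_visits_first_year=(0, 0, 0), urologist_visits_subsequent=(0, 0, 0),
            gp_visits_first_year=(0, 0, 0), gp_visits_subsequent=(0, 0, 0),
            severe_cystoscopies_per_year=0.0, incontinence_visits_per_year=0.0)
        for state in (HealthState.MILD, HealthState.MODERATE, HealthState.SEVERE):
            assert state_cycle_cost(state, True, empty, PUBLIC_COSTS) == 0.0
        assert state_cycle_cost("incontinent", False, empty, PUBLIC_COSTS) == 0.0

    def test_incontinence_visit_schedule(self):
        got = state_cycle_cost("incontinent", False, PROFILE, PRIVATE_COSTS)
        assert got == pytest.approx(4.56 * 50.00 / 4)


class TestDrugCost:
    def test_flat3_convention(self):
        prices = DrugPrices()
        assert drug_cycle_cost("fdc", prices) == pytest.approx(90.06)
        assert drug_cycle_cost("soc", prices) == pytest.approx(37.26)

    def test_day_exact_convention(self):
        prices = DrugPrices(billing="day_exact")
        assert drug_cycle_cost("fdc", prices) == pytest.approx(30.02 * 91.25 / 30)

    def test_zero_price(self):
        assert drug_cycle_cost("fdc", DrugPrices(fdc_pack_price=0.0)) == 0.0


class TestSurgeryCost:
    def test_public_tariff_without_complications(self):
        assert surgery_cost(1, 0.0, PUBLIC_COSTS, PROFILE,
                            include_periop=False) == 1_007.00

    def test_private_tariff_with_complications(self):
        assert surgery_cost(1, 1.0, PRIVATE_COSTS, PROFILE,
                            include_periop=False) == 2_848.00

    def test_zero_procedures(self):
        assert surgery_cost(0, 0.5, PUBLIC_COSTS, PROFILE) == 0.0

    @given(n=st.floats(0, 1000), p=st.floats(0, 1))
    def test_linear_in_procedures(self, n, p):
        one = surgery_cost(1, p, PUBLIC_COSTS, PROFILE)
        assert surgery_cost(n, p, PUBLIC_COSTS, PROFILE) == pytest.approx(n * one)


class TestAurCost:
    @pytest.mark.parametrize("n,costs,expected", [
        (100, PUBLIC_COSTS, 763.00), (100, PRIVATE_COSTS, 5_000.00),
        (0, PUBLIC_COSTS, 0.0)])
    def test_tariff(self, n, costs, expected):
        assert aur_cost(n, costs) == expected


class TestCycleComponents:
    def events(self, scale=1.0):
        return CycleEvents(
            cycle=5, year=2, billable_severity=scale * np.array([70.0, 630.0, 300.0]),
            billable_incontinent=scale * 2.0, entrants=scale * 10.0,
            aur_episodes=scale * 4.0, twoc_success=scale * 2.0, twoc_fail=scale * 2.0,
            first_turps=scale * 5.0, second_turps=scale * 1.0,
            successful_procs=scale * 4.62, failed_procs=scale * 1.38,
            complications=scale * 1.2, deaths=scale * 3.0)

    def test_components_nonnegative_and_linear(self):
        pw = PathwayParams(complication_prob=0.2)
        one = cycle_component_costs(self.events(), "soc", PUBLIC_COSTS,
                                    PROFILE, DrugPrices(), pw)
        three = cycle_component_costs(self.events(3.0), "soc", PUBLIC_COSTS,
                                      PROFILE, DrugPrices(), pw)
        for c in one:
            assert one[c] >= 0
            assert three[c] == pytest.approx(3 * one[c])

    def test_fdc_drug_bill_exceeds_soc(self):
        pw = PathwayParams(complication_prob=0.2)
        soc = cycle_component_costs(self.events(), "soc", PUBLIC_COSTS,
                                    PROFILE, DrugPrices(), pw)
        fdc = cycle_component_costs(self.events(), "fdc", PUBLIC_COSTS,
                                    PROFILE, DrugPrices(), pw)
        assert fdc["drug"] > soc["drug"]
        assert fdc["consultation"] == soc["consultation"]
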