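"""Cost layer: sector tariffs, resource-use profiles and drug prices.

Costs are nominal 2013 euros, never discounted nor inflated. The payer
perspective is explored as two extreme scenarios — a public sector priced at
official reimbursement tariffs and a private sector priced at out-of-pocket
rates — which are always run separately and never blended. Yearly totals
decompose exactly into four components: consultations, surgery, AUR
episodes and drug acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .states import CycleEvents, HealthState, PathwayParams, ValidationError, severity_index

__all__ = [
    "UnitCosts",
    "ResourceProfile",
    "DrugPrices",
    "PUBLIC_COSTS",
    "PRIVATE_COSTS",
    "state_cycle_cost",
    "drug_cycle_cost",
    "surgery_cost",
    "aur_cost",
    "cycle_component_costs",
]

DAYS_PER_QUARTER = 91.25


@dataclass(frozen=True)
class UnitCosts:
    """Sector-specific unit costs in 2013 euros.

    The GP visit and initial urologist consultation tariffs are not part of
    the published fee schedules used for the other items; the shipped
    defaults (GP priced at the urologist follow-up tariff, initial
    consultation at twice it) are flagged as assumptions in the
    configuration and are overridable.
    """

    sector: str
    urologist_visit: float
    gp_visit: float
    initial_consultation: float
    serum_creatinine: float
    urodynamic_test: float
    cystoscopy: float
    surgery_no_complications: float
    surgery_with_complications: float
    aur_episode: float

    def __post_init__(self) -> None:
        if self.sector not in ("public", "private"):
            raise ValidationError("sector must be 'public' or 'private'")
        for f in ("urologist_visit", "gp_visit", "initial_consultation",
                  "serum_creatinine", "urodynamic_test", "cystoscopy",
                  "surgery_no_complications", "surgery_with_complications",
                  "aur_episode"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be nonnegative")


PUBLIC_COSTS = UnitCosts(
    sector="public", urologist_visit=10.00, gp_visit=10.00,
    initial_consultation=20.00, serum_creatinine=4.05, urodynamic_test=18.99,
    cystoscopy=4.05, surgery_no_complications=1_007.00,
    surgery_with_complications=2_127.00, aur_episode=7.63)

PRIVATE_COSTS = UnitCosts(
    sector="private", urologist_visit=50.00, gp_visit=50.00,
    initial_consultation=100.00, serum_creatinine=16.00,
    urodynamic_test=268.50, cystoscopy=650.00, surgery_no_complications=1_000.00,
    surgery_with_complications=2_848.00, aur_episode=50.00)


@dataclass(frozen=True)
class ResourceProfile:
    """Annual resource-use counts per health state, from expert-panel consensus.

    Visit counts are per patient-year and are billed quarterly at a quarter
    of the annual count. ``first year`` profiles apply during the first
    model year; subsequent years use the ``per year`` figures. The severe
    state adds an expected flexible-cystoscopy cost: the conditional yearly
    count (0.39) times the proportion of patients undergoing it (7%).
    """

    # routine care: (mild, moderate, severe)
    urologist_visits_first_year: tuple = (0.0, 2.22, 2.56)
    urologist_visits_subsequent: tuple = (1.11, 2.39, 2.78)
    gp_visits_first_year: tuple = (1.22, 2.0, 0.0)
    gp_visits_subsequent: tuple = (0.44, 2.0, 0.0)
    severe_cystoscopies_per_year: float = 0.39
    severe_cystoscopy_fraction: float = 0.07
    creatinine_tests_per_year: tuple = (0.0, 0.0, 0.0)
    # surgical pathway
    periop_consults_successful: float = 2.67
    periop_consults_unsuccessful: float = 3.89
    followup_urodynamic_tests: float = 0.06
    periop_cystoscopies: float = 1.1
    complication_followup_visits: float = 3.44
    incontinence_visits_per_year: float = 4.56

    def __post_init__(self) -> None:
        for f in ("urologist_visits_first_year", "urologist_visits_subsequent",
                  "gp_visits_first_year", "gp_visits_subsequent",
                  "creatinine_tests_per_year"):
            vals = getattr(self, f)
            if len(vals) != 3 or any(v < 0 for v in vals):
                raise ValidationError(f"{f} must be 3 nonnegative counts")
            object.__setattr__(self, f, tuple(float(v) for v in vals))
        for f in ("severe_cystoscopies_per_year", "severe_cystoscopy_fraction",
                  "periop_consults_successful", "periop_consults_unsuccessful",
                  "followup_urodynamic_tests", "periop_cystoscopies",
                  "complication_followup_visits", "incontinence_visits_per_year"):
            if getattr(self, f) < 0:
                raise ValidationError(f"{f} must be nonnegative")


@dataclass(frozen=True)
class DrugPrices:
    """Retail pack prices: FDC 30.02 EUR, tamsulosin 12.42 EUR
    (volume-weighted average of originator and generics).

    ``billing='flat3'`` charges three 30-day packs per quarterly cycle,
    matching monthly dispensing; ``'day_exact'`` charges
    91.25/days_per_pack packs instead.
    """

    fdc_pack_price: float = 30.02
    soc_pack_price: float = 12.42
    days_per_pack: float = 30.0
    billing: str = "flat3"

    def __post_init__(self) -> None:
        if self.fdc_pack_price < 0 or self.soc_pack_price < 0:
            raise ValidationError("pack prices must be nonnegative")
        if self.days_per_pack <= 0:
            raise ValidationError("days_per_pack must be positive")
        if self.billing not in ("flat3", "day_exact"):
            raise ValidationError("billing must be 'flat3' or 'day_exact'")


def state_cycle_cost(state: HealthState | str, is_first_year_in_model: bool,
                     profile: ResourceProfile, costs: UnitCosts) -> float:
    """Routine-care cost per patient per quarterly cycle for one state.

    Severity states bill a quarter of their annual urologist/GP visit counts
    (plus, for severe, the expected cystoscopy); the permanent-incontinence
    post-surgery substate bills its own visit schedule. Other post-surgery
    substates incur no routine visits.
    """
    if state in ("incontinent", HealthState.POST_SURGERY):
        return profile.incontinence_visits_per_year * costs.urologist_visit / 4.0 \
            if state == "incontinent" else 0.0
    i = severity_index(state) if isinstance(state, HealthState) else \
        severity_index({"mild": HealthState.MILD, "moderate": HealthState.MODERATE,
                        "severe": HealthState.SEVERE}[state])
    uro = (profile.urologist_visits_first_year if is_first_year_in_model
           else profile.urologist_visits_subsequent)[i]
    gp = (profile.gp_visits_first_year if is_first_year_in_model
          else profile.gp_visits_subsequent)[i]
    annual = uro * costs.urologist_visit + gp * costs.gp_visit \
        + profile.creatinine_tests_per_year[i] * costs.serum_creatinine
    if i == 2:
        annual += (profile.severe_cystoscopies_per_year
                   * profile.severe_cystoscopy_fraction * costs.cystoscopy)
    return annual / 4.0


def drug_cycle_cost(arm: str, prices: DrugPrices) -> float:
    """Drug acquisition cost per patient per quarterly cycle for one arm."""
    if arm not in ("soc", "fdc"):
        raise ValidationError("arm must be 'soc' or 'fdc'")
    pack = prices.fdc_pack_price if arm == "fdc" else prices.soc_pack_price
    packs = 3.0 if prices.billing == "flat3" else DAYS_PER_QUARTER / prices.days_per_pack
    return pack * packs


def surgery_cost(n_procedures: float, complication_prob: float, costs: UnitCosts,
                 profile: ResourceProfile, turp_success: float = 0.77,
                 include_periop: bool = True) -> float:
    """Total cost of a batch of TURP procedures.

    The tariff is the complication-probability mixture of the with/without
    tariffs. Peri-operative consultations (success/failure mix by
    ``turp_success``), peri-operative cystoscopies, follow-up urodynamic
    tests and complication follow-up visits are added unless
    ``include_periop`` is False.
    """
    if n_procedures < 0:
        raise ValidationError("n_procedures must be nonnegative")
    if not 0.0 <= complication_prob <= 1.0:
        raise ValidationError("complication_prob must be a probability")
    p = complication_prob
    tariff = (1.0 - p) * costs.surgery_no_complications + p * costs.surgery_with_complications
    total = n_procedures * tariff
    if include_periop:
        consults = (turp_success * profile.periop_consults_successful
                    + (1.0 - turp_success) * profile.periop_consults_unsuccessful)
        total += n_procedures * (
            consults * costs.urologist_visit
            + profile.periop_cystoscopies * costs.cystoscopy
            + profile.followup_urodynamic_tests * costs.urodynamic_test
            + p * profile.complication_followup_visits * costs.urologist_visit)
    return total


def aur_cost(n_episodes: float, costs: UnitCosts) -> float:
    """Cost of AUR episodes (non-elective catheterization tariff)."""
    if n_episodes < 0:
        raise ValidationError("n_episodes must be nonnegative")
    return n_episodes * costs.aur_episode


_SEV_STATES = (HealthState.MILD, HealthState.MODERATE, HealthState.SEVERE)


def cycle_component_costs(events: CycleEvents, arm: str, costs: UnitCosts,
                          profile: ResourceProfile, prices: DrugPrices,
                          pathway: PathwayParams) -> dict[str, float]:
    """Euro cost of one cycle's billable occupancy and events, by component.

    Consultations cover routine severity-state visits, incontinence
    follow-up and entrant initial consultations; surgery covers procedure
    tariffs plus peri-operative items; AUR the catheterization tariff; drug
    the per-cycle acquisition cost of severity-state patients (post-surgery
    patients receive no BPH pharmacotherapy).
    """
    first_year = events.year == 1
    consult = sum(
        events.billable_severity[i]
        * state_cycle_cost(_SEV_STATES[i], first_year, profile, costs)
        for i in range(3))
    consult += events.billable_incontinent * state_cycle_cost("incontinent", first_year, profile, costs)
    consult += events.entrants * costs.initial_consultation

    surg = 0.0
    if events.turps > 0:
        # tariff mixture on all procedures; peri-op consult mix uses the
        # realised success/failure split carried in the event tallies
        p = pathway.complication_prob
        tariff = (1.0 - p) * costs.surgery_no_complications + p * costs.surgery_with_complications
        surg = events.turps * tariff
        surg += events.successful_procs * profile.periop_consults_successful * costs.urologist_visit
        surg += events.failed_procs * profile.periop_consults_unsuccessful * costs.urologist_visit
        surg += events.turps * (profile.periop_cystoscopies * costs.cystoscopy
                                + profile.followup_urodynamic_tests * costs.urodynamic_test)
        surg += events.complications * profile.complication_followup_visits * costs.urologist_visit

    aur = aur_cost(events.aur_episodes, costs)
    drug = float(np.sum(events.billable_severity)) * drug_cycle_cost(arm, prices)
    return {"consultation": consult, "surgery": surg, "aur": aur, "drug": drug}
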