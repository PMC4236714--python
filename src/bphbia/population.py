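"""Eligible-cohort arithmetic, incidence, mortality and entrant flow.

The model population is the prevalent pool of men aged >=50 with moderate to
severe BPH (census x prevalence x moderate/severe fraction), distributed
across the three symptom-severity states at baseline. New patients enter
from the second model year onward at the BPH/LUTS incidence rate quoted per
1,000 man-years in the general older-male population, so the entrant base is
the full census, not the prevalent pool. Mortality is a single
age-aggregated annual risk converted to a quarterly probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .states import ValidationError

__all__ = [
    "PopulationConfig",
    "eligible_population",
    "incidence_rate_per_1000py",
    "annual_to_cycle_prob",
    "entrants_for_cycle",
]


def _check_prob(name: str, p: float) -> float:
    p = float(p)
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"{name} must lie in [0, 1]; got {p}")
    return p


@dataclass(frozen=True)
class PopulationConfig:
    """Epidemiological inputs defining the cohort.

    ``initial_split`` gives the baseline proportions of (mild, moderate,
    severe) symptoms among modelled patients; it must sum to 1. The default
    annual mortality risk is an age-aggregated placeholder for men >50 and is
    flagged as an assumption in the shipped configuration.
    """

    census_males_50plus: float = 1_724_867
    prevalence: float = 0.30
    moderate_severe_fraction: float = 0.63
    incidence_events: float = 2_090
    incidence_person_years: float = 110_321
    annual_mortality_risk: float = 0.02
    initial_split: tuple = (0.07, 0.63, 0.30)

    def __post_init__(self) -> None:
        _check_prob("prevalence", self.prevalence)
        _check_prob("moderate_severe_fraction", self.moderate_severe_fraction)
        _check_prob("annual_mortality_risk", self.annual_mortality_risk)
        if self.census_males_50plus <= 0:
            raise ValidationError("census_males_50plus must be strictly positive")
        if self.incidence_events < 0:
            raise ValidationError("incidence_events must be nonnegative")
        if self.incidence_person_years <= 0:
            raise ValidationError("incidence_person_years must be strictly positive")
        split = np.asarray(self.initial_split, dtype=float)
        if split.shape != (3,):
            raise ValidationError("initial_split must have exactly 3 proportions")
        if np.any(split < 0) or np.any(split > 1):
            raise ValidationError("initial_split proportions must lie in [0, 1]")
        if abs(split.sum() - 1.0) > 1e-12:
            raise ValidationError(f"initial_split must sum to 1; got {split.sum()!r}")
        object.__setattr__(self, "initial_split", tuple(float(x) for x in split))

    @property
    def eligible(self) -> float:
        """Unrounded eligible cohort (fractional persons are kept internally)."""
        return self.census_males_50plus * self.prevalence * self.moderate_severe_fraction

    @property
    def incidence_rate(self) -> float:
        return incidence_rate_per_1000py(self.incidence_events, self.incidence_person_years)


def eligible_population(census: float, prevalence: float, ms_fraction: float) -> int:
    """Number of men eligible for the model: census x prevalence x fraction
    with moderate-to-severe symptoms, rounded to the nearest person.
    """
    if census < 0:
        raise ValidationError("census must be nonnegative")
    _check_prob("prevalence", prevalence)
    _check_prob("ms_fraction", ms_fraction)
    return int(round(census * prevalence * ms_fraction))


def incidence_rate_per_1000py(events: float, person_years: float) -> float:
    """Incidence expressed per 1,000 man-years."""
    if person_years <= 0:
        raise ValidationError("person_years must be strictly positive")
    if events < 0:
        raise ValidationError("events must be nonnegative")
    return 1000.0 * events / person_years


def annual_to_cycle_prob(p_annual: float, cycles_per_year: int = 4) -> float:
    """Convert an annual risk to a per-cycle probability.

    Uses the standard constant-hazard relation
    ``p_cycle = 1 - (1 - p_annual)**(1/cycles_per_year)``, so that the
    complement-product of ``cycles_per_year`` cycle probabilities recovers
    the annual risk exactly.
    """
    p_annual = _check_prob("p_annual", p_annual)
    if cycles_per_year <= 0:
        raise ValidationError("cycles_per_year must be positive")
    return 1.0 - (1.0 - p_annual) ** (1.0 / cycles_per_year)


def entrants_for_cycle(at_risk_population: float, rate_per_1000py: float,
                       cycle_years: float = 0.25, current_year: int = 1) -> float:
    """Expected incident patients entering the model in one cycle.

    Year 1 admits no entrants: the baseline prevalent cohort is assumed to
    already be under management. From year 2 onward the inflow is the
    at-risk population times the incidence rate over the cycle length.
    """
    if at_risk_population < 0 or rate_per_1000py < 0 or cycle_years < 0:
        raise ValidationError("entrant inputs must be nonnegative")
    if current_year not in (1, 2, 3, 4):
        raise ValidationError(f"current_year must be in 1..4; got {current_year}")
    if current_year == 1:
        return 0.0
    return at_risk_population * (rate_per_1000py / 1000.0) * cycle_years
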