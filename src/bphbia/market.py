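"""Market dynamics: uptake of the fixed-dose combination and year-end switching.

The new therapy enters gradually: a yearly uptake share of the first-line
market (applied to the year-1 prevalent cohort and to each year's incident
entrants) plus a year-end switching rate moving a share of standard-of-care
patients with moderate or severe symptoms onto the combination. Patients
never switch back, and remain on the combination even after regressing to
mild symptoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .states import CohortState, PostSurgerySubstate, ValidationError

__all__ = ["MarketSchedule", "allocate_entrants", "apply_switching"]


@dataclass(frozen=True)
class MarketSchedule:
    """Yearly uptake shares and year-end switching rates.

    Defaults are the observed/projected Greek market figures: uptake 2.0%,
    4.0%, 4.5%, 11.0% over the four years; switching 3.0%, 4.0%, 5.5% at
    the ends of years 1-3 (no switch after the final year).
    """

    uptake_share: dict = field(default_factory=lambda: {1: 0.020, 2: 0.040, 3: 0.045, 4: 0.110})
    switch_rate: dict = field(default_factory=lambda: {1: 0.030, 2: 0.040, 3: 0.055})

    def __post_init__(self) -> None:
        if set(self.uptake_share) != {1, 2, 3, 4}:
            raise ValidationError("uptake_share must be defined for years 1..4")
        if set(self.switch_rate) != {1, 2, 3}:
            raise ValidationError("switch_rate must be defined for year-ends 1..3 only")
        for name, d in (("uptake_share", self.uptake_share), ("switch_rate", self.switch_rate)):
            for year, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(f"{name}[{year}] must lie in [0, 1]; got {v}")

    def is_null(self) -> bool:
        return all(v == 0.0 for v in self.uptake_share.values()) and \
            all(v == 0.0 for v in self.switch_rate.values())


def allocate_entrants(entrants: float, year: int,
                      schedule: MarketSchedule) -> tuple[float, float]:
    """Split a flow of patients between the SoC and FDC arms by uptake share.

    Applies to incident entrants in every year and, with ``year=1``, to the
    initial prevalent cohort. Returns ``(soc, fdc)``.
    """
    if year not in (1, 2, 3, 4):
        raise ValidationError(f"year must be in 1..4; got {year}")
    if entrants < 0:
        raise ValidationError("entrants must be nonnegative")
    fdc = entrants * schedule.uptake_share[year]
    return entrants - fdc, fdc


def apply_switching(soc_cohort: CohortState, year_end: int,
                    schedule: MarketSchedule) -> tuple[CohortState, CohortState]:
    """Move the year-end switching share of SoC moderate/severe patients to FDC.

    Only patients currently in the moderate or severe symptom states switch;
    mild, post-surgery and dead occupancies are untouched. Returns
    ``(remaining_soc, moved)`` where ``moved`` carries the switched patients
    with their health states preserved.
    """
    if year_end not in (1, 2, 3):
        raise ValidationError(f"year_end must be in 1..3; got {year_end}")
    rate = schedule.switch_rate[year_end]

    moved_sev = np.array([0.0,
                          soc_cohort.severity[1] * rate,
                          soc_cohort.severity[2] * rate])
    remaining = soc_cohort.replace(severity=soc_cohort.severity - moved_sev)
    moved = CohortState(severity=moved_sev, post_surgery=PostSurgerySubstate(),
                        cum_deaths=0.0, cum_entrants=0.0)
    return remaining, moved
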