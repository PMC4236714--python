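"""Quarterly cohort transition engine with AUR tunnel and surgery pathway.

Each 3-month cycle applies, in a fixed documented order:

1. all-cause mortality to every alive state (deaths occur at cycle start);
2. incident entrant arrival, distributed over the severity states;
3. symptom-severity transitions (mild/moderate/severe block);
4. mid-cycle AUR resolution — emergency catheterization plus trial without
   catheter (TWOC); successes return to the exact severity state they left,
   failures proceed to TURP within the same cycle;
5. direct TURP exits from the moderate and severe states;
6. the post-surgery pathway update (first/second procedures, complications,
   permanent incontinence).

Nobody dies inside the AUR tunnel; AUR occupancy is zero at every cycle
boundary. The cohort is deterministic in expected counts: fractional
persons are allowed internally and only rounded at report time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .population import PopulationConfig, annual_to_cycle_prob, entrants_for_cycle
from .states import (
    CohortState,
    CycleEvents,
    HealthState,
    PathwayParams,
    PostSurgerySubstate,
    TransitionMatrix,
    ValidationError,
    severity_index,
)

__all__ = [
    "resolve_aur",
    "post_surgery_update",
    "step_cycle",
    "run_horizon",
    "HorizonResult",
]


def resolve_aur(n_aur: float, twoc_success: float,
                origin_state: HealthState | int) -> tuple[float, float]:
    """Resolve an AUR episode count mid-cycle.

    A fraction ``twoc_success`` of episodes end with a successful TWOC and
    return to ``origin_state``; the remainder undergo a TURP in the same
    cycle. Returns ``(returned, to_surgery)``.
    """
    if n_aur < 0:
        raise ValidationError("n_aur must be nonnegative")
    if not 0.0 <= twoc_success <= 1.0:
        raise ValidationError("twoc_success must be a probability")
    severity_index(origin_state)  # origin must be a severity state
    returned = n_aur * twoc_success
    return returned, n_aur - returned


@dataclass(frozen=True)
class _SurgeryStats:
    first_turps: float
    second_turps: float
    successful: float
    failed: float
    complications: float


def post_surgery_update(substate: PostSurgerySubstate, params: PathwayParams,
                        new_first_turps: float = 0.0,
                        ) -> tuple[PostSurgerySubstate, _SurgeryStats]:
    """Advance the post-surgery pathway by one cycle.

    Patients pending a second procedure (failed first TURP), plus a
    ``relapse_prob`` share of those stable after a successful first TURP,
    undergo the second and final TURP this cycle and settle into the
    stable-after-second substate regardless of outcome. Newly operated
    patients (``new_first_turps``) split success/failure by
    ``turp_success``; failures await the second procedure next cycle.
    ``incontinence_prob`` diverts a share of each settling group to the
    permanent-incontinence substate. ``complication_prob`` tags procedures
    for the with-complications tariff; it does not alter patient flow.
    """
    if new_first_turps < 0:
        raise ValidationError("new_first_turps must be nonnegative")
    p = params

    relapsers = p.relapse_prob * substate.stable_first
    second_n = substate.pending_second + relapsers

    succ1 = new_first_turps * p.turp_success
    fail1 = new_first_turps - succ1

    inc_from_first = succ1 * p.incontinence_prob
    inc_from_second = second_n * p.incontinence_prob

    n_procs = new_first_turps + second_n
    complications = n_procs * p.complication_prob

    new = PostSurgerySubstate(
        stable_first=substate.stable_first - relapsers + (succ1 - inc_from_first),
        pending_second=fail1,
        stable_second=substate.stable_second + (second_n - inc_from_second),
        incontinent=substate.incontinent + inc_from_first + inc_from_second,
        cum_complications=substate.cum_complications + complications,
    )
    stats = _SurgeryStats(
        first_turps=new_first_turps,
        second_turps=second_n,
        successful=n_procs * p.turp_success,
        failed=n_procs * (1.0 - p.turp_success),
        complications=complications,
    )
    return new, stats


def step_cycle(state: CohortState, matrix: TransitionMatrix, cycle_mortality: float,
               entrants: float, pathway: PathwayParams,
               entrant_split=(0.07, 0.63, 0.30), cycle: int = 1,
               initial_cohort: float | None = None,
               ) -> tuple[CohortState, CycleEvents]:
    """Advance the cohort by one quarterly cycle.

    ``entrant_split`` distributes incident entrants over the severity
    states. If ``initial_cohort`` is given, person-mass conservation is
    checked at the new boundary and a :class:`ConservationError` raised on
    drift beyond tolerance.
    """
    if not 0.0 <= cycle_mortality <= 1.0:
        raise ValidationError("cycle_mortality must be a probability")
    if entrants < 0:
        raise ValidationError("entrants must be nonnegative")
    matrix.validate()

    year = (cycle - 1) // 4 + 1

    # 1. all-cause mortality at cycle start, applied to every alive state
    surv = 1.0 - cycle_mortality
    deaths = state.alive * cycle_mortality
    sev = state.severity * surv
    ps = state.post_surgery.scaled(surv)

    # 2. incident entrants arrive
    split = np.asarray(entrant_split, dtype=float)
    sev = sev + entrants * split

    billable_severity = sev.copy()
    billable_incontinent = ps.incontinent

    # 3. severity transitions; AUR and direct-TURP exits tracked per origin
    new_sev = sev @ matrix.severity
    aur_by_origin = sev * matrix.p_aur
    direct_turp = float((sev * matrix.p_turp).sum())

    # 4. mid-cycle AUR resolution — successes return to their origin state
    twoc_returned = aur_by_origin * pathway.twoc_success
    new_sev = new_sev + twoc_returned
    aur_episodes = float(aur_by_origin.sum())
    twoc_success_n = float(twoc_returned.sum())
    twoc_fail_n = aur_episodes - twoc_success_n

    # 5.-6. this cycle's first TURPs feed the post-surgery pathway
    new_first = direct_turp + twoc_fail_n
    ps, stats = post_surgery_update(ps, pathway, new_first_turps=new_first)

    new_state = CohortState(
        severity=new_sev,
        post_surgery=ps,
        cum_deaths=state.cum_deaths + deaths,
        cum_entrants=state.cum_entrants + entrants,
    )
    if initial_cohort is not None:
        new_state.check_conservation(initial_cohort)

    events = CycleEvents(
        cycle=cycle,
        year=year,
        billable_severity=billable_severity,
        billable_incontinent=billable_incontinent,
        entrants=entrants,
        aur_episodes=aur_episodes,
        twoc_success=twoc_success_n,
        twoc_fail=twoc_fail_n,
        first_turps=stats.first_turps,
        second_turps=stats.second_turps,
        successful_procs=stats.successful,
        failed_procs=stats.failed,
        complications=stats.complications,
        deaths=deaths,
    )
    return new_state, events


@dataclass(frozen=True)
class HorizonResult:
    """Boundary states (t = 0..n_cycles) and per-cycle event tallies."""

    states: tuple
    events: tuple

    def yearly_events(self) -> dict[int, dict[str, float]]:
        """Sum event tallies over each year's four cycles."""
        out: dict[int, dict[str, float]] = {}
        for ev in self.events:
            y = out.setdefault(ev.year, {
                "aur_episodes": 0.0, "turps": 0.0, "first_turps": 0.0,
                "second_turps": 0.0, "complications": 0.0, "deaths": 0.0,
                "entrants": 0.0,
            })
            y["aur_episodes"] += ev.aur_episodes
            y["turps"] += ev.turps
            y["first_turps"] += ev.first_turps
            y["second_turps"] += ev.second_turps
            y["complications"] += ev.complications
            y["deaths"] += ev.deaths
            y["entrants"] += ev.entrants
        return out


def run_horizon(initial: CohortState, matrix: TransitionMatrix,
                population: PopulationConfig, pathway: PathwayParams,
                n_cycles: int = 16, entrant_scale: float = 1.0) -> HorizonResult:
    """Run a single-arm cohort over the model horizon (default 16 cycles).

    Incident entrants arrive from year 2 onward at the configured incidence
    rate applied to the full census, scaled by ``entrant_scale`` (used when
    only an arm's share of the market receives entrants, or when the
    eligible population is restricted to a subset).
    """
    if n_cycles < 0:
        raise ValidationError("n_cycles must be nonnegative")
    cycle_mort = annual_to_cycle_prob(population.annual_mortality_risk)
    rate = population.incidence_rate
    initial_cohort = initial.alive

    states = [initial]
    events = []
    state = initial
    for cycle in range(1, n_cycles + 1):
        year = (cycle - 1) // 4 + 1
        entrants = entrant_scale * entrants_for_cycle(
            population.census_males_50plus, rate, 0.25, min(year, 4))
        state, ev = step_cycle(state, matrix, cycle_mort, entrants, pathway,
                               entrant_split=population.initial_split,
                               cycle=cycle, initial_cohort=initial_cohort)
        states.append(state)
        events.append(ev)
    return HorizonResult(states=tuple(states), events=tuple(events))
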