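"""Scenario orchestration and budget-impact computation.

Two worlds are compared, always per sector: a standard-of-care world in
which the whole cohort stays on tamsulosin monotherapy, and an
introduction world in which the dutasteride+tamsulosin fixed-dose
combination gradually captures market share (uptake on the initial cohort
and on incident entrants, year-end switching of prevalent moderate/severe
patients). The budget impact is the year-by-year difference in total cost,
decomposed exactly into consultations, surgery, AUR and drug acquisition,
alongside the TURPs and AUR episodes avoided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig
from .costing import cycle_component_costs
from .engine import step_cycle
from .market import allocate_entrants, apply_switching
from .population import annual_to_cycle_prob, entrants_for_cycle
from .states import CohortState, ValidationError

__all__ = ["ScenarioResult", "BudgetImpact", "run_world", "budget_impact",
           "clinical_summary", "simulate_two_arms"]

COMPONENTS = ("consultation", "surgery", "aur", "drug")


@dataclass(frozen=True)
class ScenarioResult:
    """Per-year cost components and clinical event counts for one world.

    All values are unrounded expectations; rounding to whole euros/patients
    happens only at report (CSV) time. ``turps``/``aur_episodes`` may be
    None when a result is built from cost tables alone.
    """

    sector: str
    world: str
    consultation: np.ndarray
    surgery: np.ndarray
    aur: np.ndarray
    drug: np.ndarray
    turps: np.ndarray | None = None
    aur_episodes: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = None
        for f in ("consultation", "surgery", "aur", "drug"):
            arr = np.asarray(getattr(self, f), dtype=float)
            object.__setattr__(self, f, arr)
            if np.any(arr < 0):
                raise ValidationError(f"{f} costs must be nonnegative")
            n = len(arr) if n is None else n
            if len(arr) != n:
                raise ValidationError("cost components must cover the same years")
        for f in ("turps", "aur_episodes"):
            v = getattr(self, f)
            if v is not None:
                object.__setattr__(self, f, np.asarray(v, dtype=float))

    @property
    def years(self) -> np.ndarray:
        return np.arange(1, len(self.consultation) + 1)

    @property
    def total(self) -> np.ndarray:
        """Total yearly cost — exactly the sum of the four components."""
        return self.consultation + self.surgery + self.aur + self.drug

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "year": self.years, "consultation_cost": self.consultation,
            "surgery_cost": self.surgery, "aur_cost": self.aur,
            "drug_cost": self.drug, "total_cost": self.total,
        })
        if self.turps is not None:
            df["turps"] = self.turps
        if self.aur_episodes is not None:
            df["aur_episodes"] = self.aur_episodes
        df.insert(0, "sector", self.sector)
        df.insert(1, "world", self.world)
        return df


@dataclass(frozen=True)
class BudgetImpact:
    """Year-by-year difference (introduction world minus SoC world)."""

    sector: str
    consultation: np.ndarray
    surgery: np.ndarray
    aur: np.ndarray
    drug: np.ndarray
    net: np.ndarray
    percent: np.ndarray
    avoided_turps: np.ndarray | None = None
    avoided_aur: np.ndarray | None = None

    @property
    def years(self) -> np.ndarray:
        return np.arange(1, len(self.net) + 1)

    @property
    def cumulative_net(self) -> float:
        return float(self.net.sum())

    @property
    def cumulative_avoided_turps(self) -> float | None:
        return None if self.avoided_turps is None else float(self.avoided_turps.sum())

    @property
    def cumulative_avoided_aur(self) -> float | None:
        return None if self.avoided_aur is None else float(self.avoided_aur.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "year": self.years, "consultation_offset": self.consultation,
            "surgery_offset": self.surgery, "aur_offset": self.aur,
            "drug_offset": self.drug, "net_impact": self.net,
            "percent_impact": self.percent,
        })
        if self.avoided_turps is not None:
            df["avoided_turps"] = self.avoided_turps
        if self.avoided_aur is not None:
            df["avoided_aur"] = self.avoided_aur
        df.insert(0, "sector", self.sector)
        return df


def simulate_two_arms(config: ModelConfig, with_fdc: bool = True):
    """Run the cohort over the horizon, split between the SoC and FDC arms.

    Returns ``{"soc": [...CycleEvents...], "fdc": [...]}`` plus the final
    per-arm states. The FDC arm receives its uptake share of the initial
    cohort and of each year's entrants; at the end of years 1-3 the
    switching share of SoC moderate/severe patients moves across, between
    cycles, before the next cycle's mortality. With ``with_fdc=False`` the
    whole cohort runs on the SoC matrix.
    """
    popn = config.population_config()
    schedule = config.market_schedule()
    pathway = config.pathway_params()
    mat = {"soc": config.matrix("soc"), "fdc": config.matrix("fdc")}
    n_cycles = config.n_cycles
    cycle_mort = annual_to_cycle_prob(popn.annual_mortality_risk)
    rate = popn.incidence_rate

    initial_n = popn.eligible * config.cohort_scale
    if with_fdc:
        soc0, fdc0 = allocate_entrants(initial_n, 1, schedule)
    else:
        soc0, fdc0 = initial_n, 0.0

    states = {"soc": CohortState.from_split(soc0, popn.initial_split),
              "fdc": CohortState.from_split(fdc0, popn.initial_split)}
    base = {"soc": soc0, "fdc": fdc0}  # conservation baseline incl. switch transfers
    events: dict[str, list] = {"soc": [], "fdc": []}

    for cycle in range(1, n_cycles + 1):
        year = min((cycle - 1) // 4 + 1, 4)
        total_entrants = config.cohort_scale * entrants_for_cycle(
            popn.census_males_50plus, rate, 0.25, year)
        if with_fdc:
            e_soc, e_fdc = allocate_entrants(total_entrants, year, schedule)
        else:
            e_soc, e_fdc = total_entrants, 0.0
        for arm, ent in (("soc", e_soc), ("fdc", e_fdc)):
            states[arm], ev = step_cycle(
                states[arm], mat[arm], cycle_mort, ent, pathway,
                entrant_split=popn.initial_split, cycle=cycle,
                initial_cohort=base[arm])
            events[arm].append(ev)
        # year-end switching between cycles 4k and 4k+1
        if with_fdc and cycle % 4 == 0 and cycle < n_cycles and (cycle // 4) in (1, 2, 3):
            soc_new, moved = apply_switching(states["soc"], cycle // 4, schedule)
            moved_mass = moved.alive
            states["soc"] = soc_new
            states["fdc"] = states["fdc"].replace(
                severity=states["fdc"].severity + moved.severity)
            base["soc"] -= moved_mass
            base["fdc"] += moved_mass
    return events, states


def run_world(world: str, sector: str, config: ModelConfig) -> ScenarioResult:
    """Simulate one world and cost it for one sector.

    ``world`` is ``"soc_only"`` or ``"with_fdc"``. Cost components and
    event tallies are summed across arms within each year.
    """
    if world not in ("soc_only", "with_fdc"):
        raise ValidationError("world must be 'soc_only' or 'with_fdc'")
    costs = config.unit_costs(sector)
    profile = config.resource()
    prices = config.drug_prices()
    pathway = config.pathway_params()

    events, _ = simulate_two_arms(config, with_fdc=(world == "with_fdc"))
    ny = config.horizon_years
    comp = {c: np.zeros(ny) for c in COMPONENTS}
    turps = np.zeros(ny)
    aur_ep = np.zeros(ny)
    for arm, evs in events.items():
        for ev in evs:
            cc = cycle_component_costs(ev, arm, costs, profile, prices, pathway)
            yi = ev.year - 1
            for c in COMPONENTS:
                comp[c][yi] += cc[c]
            turps[yi] += ev.turps
            aur_ep[yi] += ev.aur_episodes
    return ScenarioResult(sector=sector, world=world,
                          consultation=comp["consultation"], surgery=comp["surgery"],
                          aur=comp["aur"], drug=comp["drug"],
                          turps=turps, aur_episodes=aur_ep)


def budget_impact(soc: ScenarioResult, fdc: ScenarioResult) -> BudgetImpact:
    """Budget impact of the introduction world relative to the SoC world.

    The net impact equals the sum of the four component differences
    exactly; the percent impact is the net divided by the SoC world's total
    for the same year and sector, times 100.
    """
    if soc.sector != fdc.sector:
        raise ValidationError(
            f"sector mismatch: {soc.sector!r} vs {fdc.sector!r}")
    if len(soc.total) != len(fdc.total):
        raise ValidationError("horizon mismatch between scenarios")
    diffs = {c: getattr(fdc, c) - getattr(soc, c) for c in COMPONENTS}
    net = sum(diffs.values())
    with np.errstate(divide="ignore", invalid="ignore"):
        percent = np.where(soc.total > 0, 100.0 * net / soc.total, 0.0)
    avoided_t = avoided_a = None
    if soc.turps is not None and fdc.turps is not None:
        avoided_t = soc.turps - fdc.turps
    if soc.aur_episodes is not None and fdc.aur_episodes is not None:
        avoided_a = soc.aur_episodes - fdc.aur_episodes
    return BudgetImpact(sector=soc.sector, consultation=diffs["consultation"],
                        surgery=diffs["surgery"], aur=diffs["aur"],
                        drug=diffs["drug"], net=net, percent=percent,
                        avoided_turps=avoided_t, avoided_aur=avoided_a)


def clinical_summary(soc: ScenarioResult, fdc: ScenarioResult) -> pd.DataFrame:
    """Yearly and cumulative avoided TURPs and AUR episodes.

    The cumulative row is the exact sum of the yearly rows.
    """
    if soc.turps is None or fdc.turps is None or \
            soc.aur_episodes is None or fdc.aur_episodes is None:
        raise ValidationError("clinical summary requires event tallies in both scenarios")
    df = pd.DataFrame({
        "year": [str(y) for y in soc.years],
        "soc_turps": soc.turps, "soc_aur_episodes": soc.aur_episodes,
        "fdc_world_turps": fdc.turps, "fdc_world_aur_episodes": fdc.aur_episodes,
        "avoided_turps": soc.turps - fdc.turps,
        "avoided_aur_episodes": soc.aur_episodes - fdc.aur_episodes,
    })
    total = df.drop(columns="year").sum()
    total["year"] = "total"
    return pd.concat([df, total.to_frame().T], ignore_index=True)[df.columns]
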