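"""Model configuration: schema, validation, YAML round-trip.

Every model input — epidemiology, transition matrices for both arms, market
schedule, sector tariffs, resource profiles, drug prices and pathway
probabilities — lives in one structured document. Validation is strict:
unknown keys are errors (no silent typos) and all failures are reported at
once, naming the offending field. Parameters that are modelling
assumptions rather than published values are listed under ``assumed`` and
echoed in the run manifest.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from .costing import DrugPrices, ResourceProfile, UnitCosts
from .market import MarketSchedule
from .population import PopulationConfig
from .states import PathwayParams, TransitionMatrix, ValidationError

__all__ = ["ModelConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """Configuration failed validation; the message lists every failure."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PopulationSection(_Strict):
    census_males_50plus: float = 1_724_867
    prevalence: float = Field(0.30, ge=0.0, le=1.0)
    moderate_severe_fraction: float = Field(0.63, ge=0.0, le=1.0)
    incidence_events: float = Field(2_090, ge=0.0)
    incidence_person_years: float = Field(110_321, gt=0.0)
    annual_mortality_risk: float = Field(0.02, ge=0.0, le=1.0)
    initial_split: list[float] = Field(default_factory=lambda: [0.07, 0.63, 0.30])

    def to_domain(self) -> PopulationConfig:
        return PopulationConfig(
            census_males_50plus=self.census_males_50plus,
            prevalence=self.prevalence,
            moderate_severe_fraction=self.moderate_severe_fraction,
            incidence_events=self.incidence_events,
            incidence_person_years=self.incidence_person_years,
            annual_mortality_risk=self.annual_mortality_risk,
            initial_split=tuple(self.initial_split),
        )


class MarketSection(_Strict):
    uptake_share: dict[int, float] = Field(
        default_factory=lambda: {1: 0.020, 2: 0.040, 3: 0.045, 4: 0.110})
    switch_rate: dict[int, float] = Field(
        default_factory=lambda: {1: 0.030, 2: 0.040, 3: 0.055})

    def to_domain(self) -> MarketSchedule:
        return MarketSchedule(uptake_share=dict(self.uptake_share),
                              switch_rate=dict(self.switch_rate))


class PathwaySection(_Strict):
    twoc_success: float = Field(0.5, ge=0.0, le=1.0)
    turp_success: float = Field(0.77, ge=0.0, le=1.0)
    relapse_prob: float = Field(0.0, ge=0.0, le=1.0)
    # No default: this probability comes from clinical guidelines, is not a
    # published model input, and must be an explicit choice.
    complication_prob: float = Field(..., ge=0.0, le=1.0)
    incontinence_prob: float = Field(0.01, ge=0.0, le=1.0)

    def to_domain(self) -> PathwayParams:
        return PathwayParams(twoc_success=self.twoc_success,
                             turp_success=self.turp_success,
                             relapse_prob=self.relapse_prob,
                             complication_prob=self.complication_prob,
                             incontinence_prob=self.incontinence_prob)


class UnitCostSection(_Strict):
    urologist_visit: float = Field(ge=0.0)
    gp_visit: float = Field(ge=0.0)
    initial_consultation: float = Field(ge=0.0)
    serum_creatinine: float = Field(ge=0.0)
    urodynamic_test: float = Field(ge=0.0)
    cystoscopy: float = Field(ge=0.0)
    surgery_no_complications: float = Field(ge=0.0)
    surgery_with_complications: float = Field(ge=0.0)
    aur_episode: float = Field(ge=0.0)

    def to_domain(self, sector: str) -> UnitCosts:
        return UnitCosts(sector=sector, **self.model_dump())


_PUBLIC = dict(urologist_visit=10.00, gp_visit=10.00, initial_consultation=20.00,
               serum_creatinine=4.05, urodynamic_test=18.99, cystoscopy=4.05,
               surgery_no_complications=1_007.00,
               surgery_with_complications=2_127.00, aur_episode=7.63)
_PRIVATE = dict(urologist_visit=50.00, gp_visit=50.00, initial_consultation=100.00,
                serum_creatinine=16.00, urodynamic_test=268.50, cystoscopy=650.00,
                surgery_no_complications=1_000.00,
                surgery_with_complications=2_848.00, aur_episode=50.00)


class CostsSection(_Strict):
    public: UnitCostSection = Field(default_factory=lambda: UnitCostSection(**_PUBLIC))
    private: UnitCostSection = Field(default_factory=lambda: UnitCostSection(**_PRIVATE))


class ResourceSection(_Strict):
    urologist_visits_first_year: list[float] = Field(default_factory=lambda: [0.0, 2.22, 2.56])
    urologist_visits_subsequent: list[float] = Field(default_factory=lambda: [1.11, 2.39, 2.78])
    gp_visits_first_year: list[float] = Field(default_factory=lambda: [1.22, 2.0, 0.0])
    gp_visits_subsequent: list[float] = Field(default_factory=lambda: [0.44, 2.0, 0.0])
    severe_cystoscopies_per_year: float = Field(0.39, ge=0.0)
    severe_cystoscopy_fraction: float = Field(0.07, ge=0.0, le=1.0)
    creatinine_tests_per_year: list[float] = Field(default_factory=lambda: [0.0, 0.0, 0.0])
    periop_consults_successful: float = Field(2.67, ge=0.0)
    periop_consults_unsuccessful: float = Field(3.89, ge=0.0)
    followup_urodynamic_tests: float = Field(0.06, ge=0.0)
    periop_cystoscopies: float = Field(1.1, ge=0.0)
    complication_followup_visits: float = Field(3.44, ge=0.0)
    incontinence_visits_per_year: float = Field(4.56, ge=0.0)

    def to_domain(self) -> ResourceProfile:
        d = self.model_dump()
        for k in ("urologist_visits_first_year", "urologist_visits_subsequent",
                  "gp_visits_first_year", "gp_visits_subsequent",
                  "creatinine_tests_per_year"):
            d[k] = tuple(d[k])
        return ResourceProfile(**d)


class DrugSection(_Strict):
    fdc_pack_price: float = Field(30.02, ge=0.0)
    soc_pack_price: float = Field(12.42, ge=0.0)
    days_per_pack: float = Field(30.0, gt=0.0)
    billing: Literal["flat3", "day_exact"] = "flat3"

    def to_domain(self) -> DrugPrices:
        return DrugPrices(**self.model_dump())


class MatrixSection(_Strict):
    severity: list[list[float]]
    aur: list[float]
    turp: list[float]

    def to_domain(self, arm: str) -> TransitionMatrix:
        return TransitionMatrix(arm=arm,
                                severity=np.asarray(self.severity, dtype=float),
                                p_aur=np.asarray(self.aur, dtype=float),
                                p_turp=np.asarray(self.turp, dtype=float))


class TransitionsSection(_Strict):
    soc: MatrixSection
    fdc: MatrixSection


class SensitivitySection(_Strict):
    prevalence_values: list[float] = Field(default_factory=lambda: [0.20, 0.30, 0.40])
    bpv_subset_fraction: float = Field(0.5, ge=0.0, le=1.0)
    turp_success_values: list[float] = Field(default_factory=lambda: [0.88, 0.99])


class ModelConfig(_Strict):
    """Complete, validated model configuration."""

    population: PopulationSection = Field(default_factory=PopulationSection)
    market: MarketSection = Field(default_factory=MarketSection)
    pathway: PathwaySection
    costs: CostsSection = Field(default_factory=CostsSection)
    resource_profile: ResourceSection = Field(default_factory=ResourceSection)
    drugs: DrugSection = Field(default_factory=DrugSection)
    transitions: TransitionsSection
    sensitivity: SensitivitySection = Field(default_factory=SensitivitySection)
    horizon_years: int = Field(4, ge=1)
    cohort_scale: float = Field(1.0, ge=0.0, le=1.0)
    seed: int = 0
    assumed: list[str] = Field(default_factory=list)

    # -- domain accessors -------------------------------------------------
    def population_config(self) -> PopulationConfig:
        return self.population.to_domain()

    def market_schedule(self) -> MarketSchedule:
        return self.market.to_domain()

    def pathway_params(self) -> PathwayParams:
        return self.pathway.to_domain()

    def unit_costs(self, sector: str) -> UnitCosts:
        if sector not in ("public", "private"):
            raise ValidationError("sector must be 'public' or 'private'")
        return getattr(self.costs, sector).to_domain(sector)

    def resource(self) -> ResourceProfile:
        return self.resource_profile.to_domain()

    def drug_prices(self) -> DrugPrices:
        return self.drugs.to_domain()

    def matrix(self, arm: str) -> TransitionMatrix:
        if arm not in ("soc", "fdc"):
            raise ValidationError("arm must be 'soc' or 'fdc'")
        return getattr(self.transitions, arm).to_domain(arm)

    @property
    def n_cycles(self) -> int:
        return 4 * self.horizon_years

    def copy_with(self, **dotted) -> "ModelConfig":
        """Return a new config with dotted-path overrides applied,
        e.g. ``copy_with(**{"population.prevalence": 0.2})``."""
        data = self.model_dump()
        for path, value in dotted.items():
            node = data
            parts = path.split(".")
            for p in parts[:-1]:
                node = node[p]
            if parts[-1] not in node:
                raise ConfigError(f"unknown configuration field: {path}")
            node[parts[-1]] = value
        return ModelConfig(**data)


def _format_errors(exc: PydanticValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"  - {loc}: {err['msg']}")
        if loc.endswith("complication_prob") and err["type"] == "missing":
            lines.append(
                "      (the TURP complication probability comes from clinical "
                "guidelines, not from a published model input; it has no "
                "shipped default and must be chosen explicitly, e.g. 0.20)")
    return "\n".join(lines)


def load_config(path: str | Path | dict) -> ModelConfig:
    """Read and validate a model configuration from YAML (or a dict).

    Raises :class:`ConfigError` listing every failure at once; unknown keys
    are rejected.
    """
    if isinstance(path, dict):
        raw = path
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: configuration must be a mapping")
    try:
        return ModelConfig(**raw)
    except PydanticValidationError as exc:
        raise ConfigError(
            f"invalid configuration ({exc.error_count()} error(s)):\n"
            + _format_errors(exc)) from None


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration to YAML; round-trips losslessly."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
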