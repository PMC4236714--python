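"""Univariate sensitivity analysis of the net budget impact.

Three parameters are varied one at a time, everything else held at base:
BPH prevalence (base 30%, varied to 20% and 40% — percentage points, per
the reported analysis), restriction of the eligible population to the
prostate-volume-above-50cc subset, and the TURP success probability (base
and the +11/+22-point anchors 88% and 99%, applied to first and second
procedures alike). Because incident entrants only arrive from year 2, the
year-1 net impact is exactly proportional to prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import ModelConfig
from .pipeline import budget_impact, run_world
from .states import ValidationError

__all__ = ["SensitivitySpec", "run_univariate", "net_impact_by_year"]

_PARAMS = ("prevalence", "bpv_subset", "turp_success")


@dataclass(frozen=True)
class SensitivitySpec:
    """One univariate sweep: a parameter name, its values and a sector."""

    parameter: str
    values: tuple
    sector: str = "public"

    def __post_init__(self) -> None:
        if self.parameter not in _PARAMS:
            raise ValidationError(
                f"parameter must be one of {_PARAMS}; got {self.parameter!r} "
                "(univariate analysis only — one parameter per sweep)")
        if self.sector not in ("public", "private"):
            raise ValidationError("sector must be 'public' or 'private'")
        vals = tuple(float(v) for v in self.values)
        if not vals:
            raise ValidationError("values must be non-empty")
        for v in vals:
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"{self.parameter} values must lie in [0, 1]; got {v}")
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_config(cls, parameter: str, config: ModelConfig,
                    sector: str = "public") -> "SensitivitySpec":
        s = config.sensitivity
        if parameter == "prevalence":
            values = tuple(s.prevalence_values)
        elif parameter == "bpv_subset":
            values = (s.bpv_subset_fraction,)
        elif parameter == "turp_success":
            values = (config.pathway.turp_success, *s.turp_success_values)
        else:
            raise ValidationError(f"unknown sensitivity parameter {parameter!r}")
        return cls(parameter=parameter, values=values, sector=sector)


def _perturbed(config: ModelConfig, parameter: str, value: float) -> ModelConfig:
    if parameter == "prevalence":
        return config.copy_with(**{"population.prevalence": value})
    if parameter == "bpv_subset":
        return config.copy_with(cohort_scale=value)
    if parameter == "turp_success":
        return config.copy_with(**{"pathway.turp_success": value})
    raise ValidationError(f"unknown sensitivity parameter {parameter!r}")


def net_impact_by_year(config: ModelConfig, sector: str):
    """Net yearly budget impact (introduction minus SoC world) for one config."""
    soc = run_world("soc_only", sector, config)
    fdc = run_world("with_fdc", sector, config)
    return budget_impact(soc, fdc).net


def run_univariate(spec: SensitivitySpec, config: ModelConfig) -> pd.DataFrame:
    """Re-run the full pipeline once per parameter value.

    Returns a tidy table: parameter, value, sector, and the net budget
    impact for each model year. Exactly one parameter differs from base in
    each run.
    """
    rows = []
    for value in spec.values:
        net = net_impact_by_year(_perturbed(config, spec.parameter, value),
                                 spec.sector)
        row = {"parameter": spec.parameter, "value": value, "sector": spec.sector}
        row.update({f"year_{y}": net[y - 1] for y in range(1, len(net) + 1)})
        rows.append(row)
    return pd.DataFrame(rows)
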