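"""Health-state space and core containers for the BPH Markov cohort model.

The disease model tracks men with benign prostatic hyperplasia (BPH) through
six mutually exclusive health states — mild, moderate and severe lower
urinary tract symptoms (by IPSS band), acute urinary retention (AUR),
post-surgery and death — on a 3-month cycle. AUR is a tunnel state: it is
entered and resolved within a single cycle, so its occupancy at every cycle
boundary is zero. The post-surgery state carries internal sub-states because
a patient may undergo at most two TURP procedures and may end up with
permanent incontinence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HealthState",
    "Severity",
    "SEVERITY_STATES",
    "TransitionMatrix",
    "PostSurgerySubstate",
    "CohortState",
    "CycleEvents",
    "PathwayParams",
    "ValidationError",
    "ConservationError",
]

#: Absolute tolerance (in persons) for cohort bookkeeping identities.
CONSERVATION_TOL = 1e-6

#: Tolerance for row-stochasticity of transition matrices.
ROW_SUM_TOL = 1e-12


class ValidationError(ValueError):
    """An input violated a model precondition."""


class ConservationError(RuntimeError):
    """Probability/person mass leaked beyond tolerance during a cycle."""


class HealthState(enum.Enum):
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"
    AUR = "aur"
    POST_SURGERY = "post_surgery"
    DEATH = "death"


class Severity(enum.IntEnum):
    """Index of the three alive symptom-severity states."""

    MILD = 0
    MODERATE = 1
    SEVERE = 2


SEVERITY_STATES = (HealthState.MILD, HealthState.MODERATE, HealthState.SEVERE)

_SEVERITY_OF = {
    HealthState.MILD: Severity.MILD,
    HealthState.MODERATE: Severity.MODERATE,
    HealthState.SEVERE: Severity.SEVERE,
}


def severity_index(state: HealthState | Severity | int) -> int:
    """Map a severity health state (or index) to its row index 0..2."""
    if isinstance(state, HealthState):
        try:
            return int(_SEVERITY_OF[state])
        except KeyError:
            raise ValidationError(f"{state} is not a symptom-severity state")
    idx = int(state)
    if idx not in (0, 1, 2):
        raise ValidationError(f"severity index out of range: {state}")
    return idx


@dataclass(frozen=True)
class TransitionMatrix:
    """Quarterly transition probabilities for one treatment arm.

    ``severity`` is the 3x3 block of moves among mild/moderate/severe;
    ``p_aur`` and ``p_turp`` are the per-state quarterly probabilities of an
    AUR episode and of a direct (non-AUR) TURP. Together each row must sum
    to 1: severity[i, :].sum() + p_aur[i] + p_turp[i] == 1. Direct TURP from
    the mild state is structurally impossible (surgery is only indicated for
    moderate/severe symptoms), so p_turp[0] must be exactly 0.
    """

    arm: str
    severity: np.ndarray
    p_aur: np.ndarray
    p_turp: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "severity", np.asarray(self.severity, dtype=float))
        object.__setattr__(self, "p_aur", np.asarray(self.p_aur, dtype=float))
        object.__setattr__(self, "p_turp", np.asarray(self.p_turp, dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.severity.shape != (3, 3):
            raise ValidationError("severity block must be 3x3")
        if self.p_aur.shape != (3,) or self.p_turp.shape != (3,):
            raise ValidationError("p_aur and p_turp must each have 3 entries")
        for name, arr in (("severity", self.severity), ("p_aur", self.p_aur), ("p_turp", self.p_turp)):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValidationError(f"{name} entries must lie in [0, 1]")
        if self.p_turp[0] != 0.0:
            raise ValidationError("direct TURP probability from the mild state must be 0")
        row_sums = self.severity.sum(axis=1) + self.p_aur + self.p_turp
        if np.any(np.abs(row_sums - 1.0) > ROW_SUM_TOL):
            raise ValidationError(f"transition rows must sum to 1; got {row_sums}")

    def row_sums(self) -> np.ndarray:
        return self.severity.sum(axis=1) + self.p_aur + self.p_turp

    def to_dict(self) -> dict:
        return {
            "severity": self.severity.tolist(),
            "aur": self.p_aur.tolist(),
            "turp": self.p_turp.tolist(),
        }

    @classmethod
    def from_dict(cls, arm: str, d: dict) -> "TransitionMatrix":
        return cls(arm=arm, severity=np.asarray(d["severity"], dtype=float),
                   p_aur=np.asarray(d["aur"], dtype=float),
                   p_turp=np.asarray(d["turp"], dtype=float))


@dataclass(frozen=True)
class PathwayParams:
    """Probabilities governing AUR resolution and the post-surgery pathway.

    twoc_success
        Probability that a trial without catheter (TWOC) after an AUR episode
        succeeds, returning the patient to the severity state they left.
    turp_success
        Probability that a TURP achieves >50% IPSS reduction. Applied to
        first and second procedures alike.
    relapse_prob
        Per-cycle probability that a patient stable after a successful first
        TURP relapses and undergoes the second (and final) procedure.
    complication_prob
        Probability that a procedure incurs complications (higher tariff and
        follow-up visits); applied to all procedures regardless of outcome.
    incontinence_prob
        Probability that an operated patient is left with total, permanent
        incontinence and its follow-up visit schedule.
    """

    twoc_success: float = 0.5
    turp_success: float = 0.77
    relapse_prob: float = 0.0
    complication_prob: float = 0.20
    incontinence_prob: float = 0.01

    def __post_init__(self) -> None:
        for name in ("twoc_success", "turp_success", "relapse_prob",
                     "complication_prob", "incontinence_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability in [0, 1]; got {v}")


@dataclass(frozen=True)
class PostSurgerySubstate:
    """Occupancy of the post-surgery state, split by surgical history.

    ``pending_second`` holds patients whose first TURP failed (<50% IPSS
    reduction) and who await the second procedure next cycle; after the
    second TURP patients stay in ``stable_second`` regardless of outcome
    (two-procedure cap). ``incontinent`` patients carry their own follow-up
    visit profile. ``cum_complications`` counts procedures with
    complications since model start.
    """

    stable_first: float = 0.0
    pending_second: float = 0.0
    stable_second: float = 0.0
    incontinent: float = 0.0
    cum_complications: float = 0.0

    def __post_init__(self) -> None:
        for name in ("stable_first", "pending_second", "stable_second", "incontinent"):
            if getattr(self, name) < -CONSERVATION_TOL:
                raise ValidationError(f"post-surgery occupancy {name} must be nonnegative")

    @property
    def total(self) -> float:
        return self.stable_first + self.pending_second + self.stable_second + self.incontinent

    def scaled(self, f: float) -> "PostSurgerySubstate":
        return PostSurgerySubstate(self.stable_first * f, self.pending_second * f,
                                   self.stable_second * f, self.incontinent * f,
                                   self.cum_complications)


@dataclass(frozen=True)
class CohortState:
    """Expected-count occupancy of the cohort at a cycle boundary.

    The AUR tunnel never appears here: every episode resolves mid-cycle, so
    boundary AUR occupancy is identically zero.
    """

    severity: np.ndarray  # (3,) mild/moderate/severe
    post_surgery: PostSurgerySubstate = field(default_factory=PostSurgerySubstate)
    cum_deaths: float = 0.0
    cum_entrants: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "severity", np.asarray(self.severity, dtype=float))
        if self.severity.shape != (3,):
            raise ValidationError("severity occupancy must have 3 entries")
        if np.any(self.severity < -CONSERVATION_TOL):
            raise ValidationError("severity occupancy must be nonnegative")

    @property
    def alive(self) -> float:
        return float(self.severity.sum()) + self.post_surgery.total

    def check_conservation(self, initial_cohort: float) -> None:
        expected = initial_cohort + self.cum_entrants
        drift = abs(self.alive + self.cum_deaths - expected)
        if drift > CONSERVATION_TOL * max(1.0, expected):
            raise ConservationError(
                f"cohort mass drifted by {drift:.3g} persons "
                f"(alive={self.alive:.6f}, dead={self.cum_deaths:.6f}, "
                f"expected={expected:.6f})")

    @classmethod
    def from_split(cls, n: float, split) -> "CohortState":
        split = np.asarray(split, dtype=float)
        return cls(severity=n * split)

    def replace(self, **kw) -> "CohortState":
        return replace(self, **kw)


@dataclass(frozen=True)
class CycleEvents:
    """Per-cycle event tallies and billable occupancies.

    ``billable_severity`` and ``billable_incontinent`` record the occupancy
    at the start of the cycle (after mortality and entrant arrival), which is
    the membership the costing layer bills for drugs and routine visits.
    """

    cycle: int
    year: int
    billable_severity: np.ndarray
    billable_incontinent: float
    entrants: float
    aur_episodes: float
    twoc_success: float
    twoc_fail: float
    first_turps: float
    second_turps: float
    successful_procs: float
    failed_procs: float
    complications: float
    deaths: float

    @property
    def turps(self) -> float:
        return self.first_turps + self.second_turps
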