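"""Synthetic generation and calibration of the unpublished model inputs.

The quarterly transition probabilities between the severity states and the
quarterly AUR/direct-TURP hazards were estimated from patient-level trial
data that are not publicly available. This module generates per-arm
matrices with the qualitatively documented structure — the combination arm
has multiplicatively lower progression, AUR and surgery hazards than the
monotherapy arm — seeded and reproducible, and can calibrate the
monotherapy hazards so that the simulated yearly TURP and AUR counts match
a supplied target table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig, PathwaySection, TransitionsSection, MatrixSection
from .engine import run_horizon
from .states import CohortState, TransitionMatrix, ValidationError

__all__ = ["EffectConfig", "generate_transition_set", "CalibrationResult",
           "calibrate_to_event_table", "default_config", "ASSUMED_PARAMETERS"]

# Configuration fields whose values are modelling assumptions, not
# published inputs; echoed in every run manifest.
ASSUMED_PARAMETERS = [
    "population.annual_mortality_risk",
    "pathway.turp_success",
    "pathway.relapse_prob",
    "pathway.complication_prob",
    "pathway.incontinence_prob",
    "costs.public.gp_visit",
    "costs.private.gp_visit",
    "costs.public.initial_consultation",
    "costs.private.initial_consultation",
    "sensitivity.bpv_subset_fraction",
    "transitions",  # synthetic stand-in for unpublished trial estimates
]


@dataclass(frozen=True)
class EffectConfig:
    """Generator settings for the per-arm quarterly transition matrices.

    The monotherapy (SoC) arm is parameterised by worsening/improvement
    probabilities between severity states and per-state AUR/direct-TURP
    hazards. The combination (FDC) arm applies multiplicative risk
    reductions (each in (0, 1]) to worsening, AUR and TURP hazards, with
    the freed mass returned to the staying probability — so the FDC arm
    stochastically dominates on staying-mild/improving. A Dirichlet jitter
    (scale 0 = deterministic) perturbs the SoC rows before the reductions
    are applied, so the dominance ordering is preserved.
    """

    # SoC severity dynamics: worsening mild->moderate, moderate->severe;
    # improvement moderate->mild, severe->moderate (quarterly)
    p_mild_to_moderate: float = 0.10
    p_moderate_to_severe: float = 0.05
    p_moderate_to_mild: float = 0.03
    p_severe_to_moderate: float = 0.04
    # quarterly event hazards per severity state (mild, moderate, severe)
    p_aur: tuple = (0.001, 0.004, 0.008)
    p_turp: tuple = (0.0, 0.003, 0.008)
    # FDC multiplicative risk reductions
    worsening_multiplier: float = 0.65
    aur_multiplier: float = 0.35
    turp_multiplier: float = 0.35
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        for name in ("worsening_multiplier", "aur_multiplier", "turp_multiplier"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValidationError(f"{name} must lie in (0, 1]; got {v}")
        for name in ("p_mild_to_moderate", "p_moderate_to_severe",
                     "p_moderate_to_mild", "p_severe_to_moderate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability")
        if self.jitter < 0:
            raise ValidationError("jitter must be nonnegative")
        if self.p_turp[0] != 0.0:
            raise ValidationError("direct TURP from mild must be 0")


def _soc_rows(effect: EffectConfig) -> np.ndarray:
    """Full 3x5 row matrix: [to_mild, to_moderate, to_severe, aur, turp]."""
    e = effect
    rows = np.zeros((3, 5))
    rows[0, :] = [0.0, e.p_mild_to_moderate, 0.0, e.p_aur[0], e.p_turp[0]]
    rows[1, :] = [e.p_moderate_to_mild, 0.0, e.p_moderate_to_severe, e.p_aur[1], e.p_turp[1]]
    rows[2, :] = [0.0, e.p_severe_to_moderate, 0.0, e.p_aur[2], e.p_turp[2]]
    for i in range(3):
        stay = 1.0 - rows[i].sum()
        if stay < 0:
            raise ValidationError(f"row {i} exit probabilities exceed 1")
        rows[i, i] = stay
    return rows


def _jitter_rows(rows: np.ndarray, seed: int, scale: float) -> np.ndarray:
    """Dirichlet perturbation on the natural-parameter scale.

    Positive entries of each row become a Dirichlet draw with concentration
    row/scale, keeping structural zeros exactly zero; scale 0 returns the
    rows unchanged. Deterministic given the seed (fixed draw order).
    """
    if scale == 0.0:
        return rows.copy()
    rng = np.random.default_rng(seed)
    out = rows.copy()
    for i in range(3):
        pos = rows[i] > 0
        alpha = rows[i, pos] / scale
        out[i, pos] = rng.dirichlet(alpha)
    return out


def _rows_to_matrix(arm: str, rows: np.ndarray) -> TransitionMatrix:
    return TransitionMatrix(arm=arm, severity=rows[:, :3].copy(),
                            p_aur=rows[:, 3].copy(), p_turp=rows[:, 4].copy())


def generate_transition_set(effect: EffectConfig) -> tuple[TransitionMatrix, TransitionMatrix]:
    """Generate the (SoC, FDC) quarterly transition-matrix pair.

    Deterministic given ``effect.seed``. With all multipliers equal to 1
    the two matrices are identical.
    """
    soc_rows = _jitter_rows(_soc_rows(effect), effect.seed, effect.jitter)

    fdc_rows = soc_rows.copy()
    # worsening moves are the above-diagonal severity entries
    for i, j in ((0, 1), (0, 2), (1, 2)):
        fdc_rows[i, j] = soc_rows[i, j] * effect.worsening_multiplier
    fdc_rows[:, 3] = soc_rows[:, 3] * effect.aur_multiplier
    fdc_rows[:, 4] = soc_rows[:, 4] * effect.turp_multiplier
    # freed mass goes to the staying probability: stay = 1 - other exits
    for i in range(3):
        off = fdc_rows[i].sum() - fdc_rows[i, i]
        fdc_rows[i, i] = 1.0 - off

    return _rows_to_matrix("soc", soc_rows), _rows_to_matrix("fdc", fdc_rows)


@dataclass(frozen=True)
class CalibrationResult:
    matrix: TransitionMatrix
    aur_scale: float
    turp_scale: float
    max_rel_error: float
    yearly_rel_errors: dict
    converged: bool
    n_evaluations: int
    message: str


def _yearly_counts(matrix: TransitionMatrix, config: ModelConfig) -> tuple[np.ndarray, np.ndarray]:
    popn = config.population_config()
    pathway = config.pathway_params()
    initial = CohortState.from_split(popn.eligible * config.cohort_scale,
                                     popn.initial_split)
    res = run_horizon(initial, matrix, popn, pathway, n_cycles=config.n_cycles)
    ye = res.yearly_events()
    years = sorted(ye)
    return (np.array([ye[y]["turps"] for y in years]),
            np.array([ye[y]["aur_episodes"] for y in years]))


def _scaled_matrix(base: TransitionMatrix, aur_scale: float, turp_scale: float) -> TransitionMatrix:
    p_aur = np.clip(base.p_aur * aur_scale, 0.0, 1.0)
    p_turp = np.clip(base.p_turp * turp_scale, 0.0, 1.0)
    sev = base.severity.copy()
    for i in range(3):
        off = sev[i].sum() - sev[i, i]
        sev[i, i] = 1.0 - off - p_aur[i] - p_turp[i]
        if sev[i, i] < 0:
            raise ValidationError("scaled hazards leave no staying probability")
    return TransitionMatrix(arm=base.arm, severity=sev, p_aur=p_aur, p_turp=p_turp)


def calibrate_to_event_table(targets_turp, targets_aur, config: ModelConfig,
                             tolerance: float = 1e-3, max_iter: int = 200,
                             base: TransitionMatrix | None = None) -> CalibrationResult:
    """Calibrate SoC event hazards to yearly TURP and AUR count targets.

    A deterministic pattern (coordinate) search over two scalar multipliers
    — one on the AUR hazards, one on the direct-TURP hazards — minimises
    the maximum yearly relative error against the targets, holding the
    severity-shift probabilities fixed. Returns the best matrix found;
    ``converged`` is True only if every yearly relative error is within
    ``tolerance``. Non-convergence returns the best-found result with a
    warning message, never silently.
    """
    t_turp = np.asarray(targets_turp, dtype=float)
    t_aur = np.asarray(targets_aur, dtype=float)
    if np.any(t_turp < 0) or np.any(t_aur < 0):
        raise ValidationError("targets must be nonnegative")
    if np.all(t_turp == 0) and np.all(t_aur == 0):
        raise ValidationError("all-zero targets are unreachable with positive hazards")
    if tolerance <= 0:
        raise ValidationError("tolerance must be positive")
    if base is None:
        base = config.matrix("soc")

    n_eval = 0

    def objective(s):
        nonlocal n_eval
        n_eval += 1
        try:
            m = _scaled_matrix(base, s[0], s[1])
        except ValidationError:
            return np.inf, None
        turps, aurs = _yearly_counts(m, config)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel_t = np.abs(turps - t_turp) / np.where(t_turp > 0, t_turp, 1.0)
            rel_a = np.abs(aurs - t_aur) / np.where(t_aur > 0, t_aur, 1.0)
        return float(max(rel_t.max(), rel_a.max())), (rel_t, rel_a)

    point = np.array([1.0, 1.0])
    best, best_rel = objective(point)
    if not np.isfinite(best):
        raise ValidationError("initial hazards are infeasible")
    if tolerance == np.inf or best <= tolerance:
        m = _scaled_matrix(base, *point)
        return CalibrationResult(m, point[0], point[1], best,
                                 {"turp": best_rel[0].tolist(), "aur": best_rel[1].tolist()},
                                 True, n_eval, "converged")

    step = 0.5
    it = 0
    while it < max_iter and step > 1e-9 and best > tolerance:
        it += 1
        improved = False
        for axis in (0, 1):
            for sign in (+1.0, -1.0):
                cand = point.copy()
                cand[axis] = max(cand[axis] + sign * step, 1e-9)
                val, rel = objective(cand)
                if val < best:
                    best, best_rel, point = val, rel, cand
                    improved = True
        if not improved:
            step *= 0.5

    matrix = _scaled_matrix(base, *point)
    converged = best <= tolerance
    msg = "converged" if converged else (
        f"warning: did not reach tolerance {tolerance:g} within {max_iter} "
        f"iterations; best max relative error {best:.3g}")
    return CalibrationResult(matrix, float(point[0]), float(point[1]), best,
                             {"turp": best_rel[0].tolist(), "aur": best_rel[1].tolist()},
                             converged, n_eval, msg)


def default_config(seed: int = 0, jitter: float = 0.0) -> ModelConfig:
    """A complete configuration: every published value at its printed
    default, synthetic transition matrices for the rest, and every assumed
    parameter listed under ``assumed``.
    """
    soc, fdc = generate_transition_set(EffectConfig(seed=seed, jitter=jitter))
    return ModelConfig(
        pathway=PathwaySection(complication_prob=0.20),
        transitions=TransitionsSection(
            soc=MatrixSection(**soc.to_dict()),
            fdc=MatrixSection(**fdc.to_dict())),
        seed=seed,
        assumed=list(ASSUMED_PARAMETERS),
    )
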