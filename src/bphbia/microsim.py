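"""Individual-level Monte Carlo counterpart of the cohort engine.

The cohort engine propagates expected counts; this module simulates the
same per-cycle mechanics — mortality at cycle start, severity transitions,
mid-cycle AUR with TWOC, direct TURPs, the two-procedure surgery pathway —
for an integer population of simulated patients. It is the independent
oracle used to validate the deterministic engine: with a common parameter
set, yearly event tallies from a large microsimulation must agree with the
cohort expectations to within binomial sampling error.

The microsimulation runs a closed cohort (no incident entrants): an
expected-count entrant stream has no exact individual-level analogue.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .states import PathwayParams, TransitionMatrix, ValidationError

__all__ = ["microsimulate"]

# patient status codes
_MILD, _MODERATE, _SEVERE = 0, 1, 2
_STABLE_FIRST, _PENDING_SECOND, _STABLE_SECOND, _INCONTINENT = 3, 4, 5, 6
_DEAD = 7


def microsimulate(n_patients: int, matrix: TransitionMatrix,
                  pathway: PathwayParams, initial_split=(0.07, 0.63, 0.30),
                  cycle_mortality: float = 0.0, n_cycles: int = 16,
                  seed: int = 0) -> pd.DataFrame:
    """Simulate ``n_patients`` individually over ``n_cycles`` quarters.

    Initial severities are assigned deterministically in the exact
    ``initial_split`` proportions (largest-remainder rounding) so that the
    only stochasticity is in the transitions. Returns one row per year
    with columns ``aur_episodes``, ``turps``, ``first_turps``,
    ``second_turps``, ``complications`` and ``deaths``.
    """
    if n_patients <= 0:
        raise ValidationError("n_patients must be positive")
    if not 0.0 <= cycle_mortality <= 1.0:
        raise ValidationError("cycle_mortality must be a probability")
    matrix.validate()
    rng = np.random.default_rng(seed)

    split = np.asarray(initial_split, dtype=float)
    counts = np.floor(n_patients * split).astype(int)
    # largest-remainder rounding to hit n_patients exactly
    rem = n_patients - counts.sum()
    order = np.argsort(-(n_patients * split - counts))
    counts[order[:rem]] += 1
    status = np.repeat(np.arange(3), counts)

    # per-severity cumulative destination distribution:
    # [to_mild, to_moderate, to_severe, aur, turp]
    rows = np.hstack([matrix.severity, matrix.p_aur[:, None], matrix.p_turp[:, None]])
    cum = np.cumsum(rows, axis=1)
    cum[:, -1] = 1.0  # guard against rounding

    records = []
    for cycle in range(1, n_cycles + 1):
        year = (cycle - 1) // 4 + 1
        tallies = dict(aur_episodes=0, turps=0, first_turps=0, second_turps=0,
                       complications=0.0, deaths=0)

        # 1. mortality at cycle start (nobody is in the AUR tunnel here)
        alive = status != _DEAD
        if cycle_mortality > 0:
            dies = alive & (rng.random(status.shape) < cycle_mortality)
            status[dies] = _DEAD
            tallies["deaths"] = int(dies.sum())

        # 2. second TURPs: pending failures plus relapsing first successes,
        #    measured before this cycle's new outcomes are assigned
        second = status == _PENDING_SECOND
        if pathway.relapse_prob > 0:
            relapse = (status == _STABLE_FIRST) & \
                (rng.random(status.shape) < pathway.relapse_prob)
            second = second | relapse
        n_second = int(second.sum())
        if n_second:
            inc = rng.random(n_second) < pathway.incontinence_prob
            dest = np.where(inc, _INCONTINENT, _STABLE_SECOND)
            status[second] = dest

        # 3. severity transitions with AUR and direct-TURP exits.
        # Membership is snapshotted first so nobody transitions twice in
        # one cycle.
        new_first = np.zeros(status.shape, dtype=bool)
        idx_by_state = [np.flatnonzero(status == s) for s in range(3)]
        for s in range(3):
            idx = idx_by_state[s]
            n = len(idx)
            if n == 0:
                continue
            dest = np.searchsorted(cum[s], rng.random(n), side="right")
            dest = np.minimum(dest, 4)
            # AUR: mid-cycle TWOC, success returns to the origin state
            aur_sel = idx[dest == 3]
            tallies["aur_episodes"] += len(aur_sel)
            if len(aur_sel):
                ok = rng.random(len(aur_sel)) < pathway.twoc_success
                new_first[aur_sel[~ok]] = True  # failed TWOC -> TURP
                # successes keep status s (origin state), nothing to do
            # direct TURP
            turp_sel = idx[dest == 4]
            new_first[turp_sel] = True
            # pure severity moves
            move_sel = dest < 3
            status[idx[move_sel]] = dest[move_sel]

        # 4. first-TURP outcomes
        n_first = int(new_first.sum())
        if n_first:
            ok = rng.random(n_first) < pathway.turp_success
            inc = rng.random(n_first) < pathway.incontinence_prob
            dest = np.where(ok, np.where(inc, _INCONTINENT, _STABLE_FIRST),
                            _PENDING_SECOND)
            status[new_first] = dest

        n_procs = n_first + n_second
        tallies["first_turps"] = n_first
        tallies["second_turps"] = n_second
        tallies["turps"] = n_procs
        tallies["complications"] = float(
            (rng.random(n_procs) < pathway.complication_prob).sum())
        tallies["year"] = year
        records.append(tallies)

    df = pd.DataFrame(records).groupby("year").sum()
    return df.reset_index()
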