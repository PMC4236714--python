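import numpy as np
import pytest
from hypothesis import given, strategies as st

from bphbia import (
    CohortState,
    HealthState,
    PathwayParams,
    PopulationConfig,
    PostSurgerySubstate,
    TransitionMatrix,
    ValidationError,
    post_surgery_update,
    resolve_aur,
    run_horizon,
    step_cycle,
)

IDENTITY = TransitionMatrix(arm="soc", severity=np.eye(3),
                            p_aur=np.zeros(3), p_turp=np.zeros(3))


def simple_matrix(p_aur=(0.0, 0.01, 0.0), p_turp=(0.0, 0.0, 0.0)):
    sev = np.eye(3)
    for i in range(3):
        sev[i, i] = 1.0 - p_aur[i] - p_turp[i]
    return TransitionMatrix(arm="soc", severity=sev, p_aur=np.array(p_aur),
                            p_turp=np.array(p_turp))


@st.composite
def valid_matrices(draw):
    rows = []
    aur, turp = [], []
    for i in range(3):
        raw = np.array([draw(st.floats(0.01, 1.0)) for _ in range(5)])
        if i == 0:
            raw[4] = 0.0  # no direct TURP from mild
        raw = raw / raw.sum()
        rows.append(raw[:3])
        aur.append(raw[3])
        turp.append(raw[4])
    sev = np.array(rows)
    # renormalize exactly
    for i in range(3):
        sev[i, i] += 1.0 - (sev[i].sum() + aur[i] + turp[i])
    return TransitionMatrix(arm="soc", severity=sev, p_aur=np.array(aur),
                            p_turp=np.array(turp))


class TestMatrixValidation:
    def test_rows_must_be_stochastic(self):
        with pytest.raises(ValidationError):
            TransitionMatrix(arm="soc", severity=np.eye(3) * 0.9,
                             p_aur=np.zeros(3), p_turp=np.zeros(3))

    def test_mild_direct_turp_forbidden(self):
        sev = np.eye(3)
        sev[0, 0] = 0.99
        with pytest.raises(ValidationError):
            TransitionMatrix(arm="soc", severity=sev, p_aur=np.zeros(3),
                             p_turp=np.array([0.01, 0.0, 0.0]))


class TestResolveAur:
    @pytest.mark.parametrize("n,p,origin,expected", [
        (100, 0.5, HealthState.SEVERE, (50.0, 50.0)),
        (0, 0.9, HealthState.MILD, (0.0, 0.0)),
        (80, 0.25, HealthState.MODERATE, (20.0, 60.0)),
    ])
    def test_split(self, n, p, origin, expected):
        assert resolve_aur(n, p, origin) == expected

    @given(n=st.floats(0, 1e6), p=st.floats(0, 1))
    def test_tunnel_fully_vacated(self, n, p):
        returned, to_surgery = resolve_aur(n, p, HealthState.MODERATE)
        assert returned + to_surgery == pytest.approx(n)

    def test_origin_must_be_severity_state(self):
        with pytest.raises(ValidationError):
            resolve_aur(10, 0.5, HealthState.DEATH)


class TestPostSurgeryUpdate:
    def test_perfect_success_never_schedules_second_turp(self):
        ps = PostSurgerySubstate()
        params = PathwayParams(turp_success=1.0, relapse_prob=0.0,
                               complication_prob=0.0, incontinence_prob=0.0)
        for _ in range(5):
            ps, stats = post_surgery_update(ps, params, new_first_turps=100.0)
            assert stats.second_turps == 0.0
            assert ps.pending_second == 0.0

    def test_success_failure_split(self):
        params = PathwayParams(turp_success=0.77, complication_prob=0.0,
                               incontinence_prob=0.0)
        ps, stats = post_surgery_update(PostSurgerySubstate(), params,
                                        new_first_turps=100.0)
        assert ps.stable_first == pytest.approx(77.0)
        assert ps.pending_second == pytest.approx(23.0)
        # the 23 failures undergo the second procedure next cycle
        ps2, stats2 = post_surgery_update(ps, params)
        assert stats2.second_turps == pytest.approx(23.0)
        assert ps2.pending_second == 0.0
        assert ps2.stable_second == pytest.approx(23.0)

    def test_complication_tagging(self):
        params = PathwayParams(complication_prob=0.2, incontinence_prob=0.0)
        _, stats = post_surgery_update(PostSurgerySubstate(), params,
                                       new_first_turps=100.0)
        assert stats.complications == pytest.approx(20.0)

    @given(n=st.floats(0, 1e5), succ=st.floats(0, 1), inc=st.floats(0, 1),
           rel=st.floats(0, 1))
    def test_mass_conserved(self, n, succ, inc, rel):
        params = PathwayParams(turp_success=succ, relapse_prob=rel,
                               complication_prob=0.1, incontinence_prob=inc)
        before = PostSurgerySubstate(stable_first=50, pending_second=20,
                                     stable_second=30, incontinent=5)
        after, _ = post_surgery_update(before, params, new_first_turps=n)
        assert after.total == pytest.approx(before.total + n, rel=1e-12)


class TestStepCycle:
    def test_identity_is_a_noop(self):
        state = CohortState(severity=np.array([100.0, 200.0, 300.0]))
        new, ev = step_cycle(state, IDENTITY, 0.0, 0.0,
                             PathwayParams(), initial_cohort=600.0)
        np.testing.assert_allclose(new.severity, state.severity)
        assert ev.aur_episodes == 0 and ev.turps == 0 and ev.deaths == 0

    def test_expected_aur_pathway_counts(self):
        # 1,000 moderate patients, quarterly AUR probability 1%, TWOC 50%:
        # 10 episodes, 5 return, 5 proceed to TURP
        state = CohortState(severity=np.array([0.0, 1000.0, 0.0]))
        matrix = simple_matrix(p_aur=(0.0, 0.01, 0.0))
        new, ev = step_cycle(state, matrix, 0.0, 0.0,
                             PathwayParams(twoc_success=0.5),
                             initial_cohort=1000.0)
        assert ev.aur_episodes == pytest.approx(10.0)
        assert ev.twoc_success == pytest.approx(5.0)
        assert ev.first_turps == pytest.approx(5.0)
        assert new.severity[1] == pytest.approx(995.0)

    @given(matrix=valid_matrices(), mort=st.floats(0, 0.1),
           entrants=st.floats(0, 1000))
    def test_conservation(self, matrix, mort, entrants):
        state = CohortState(severity=np.array([700.0, 6300.0, 3000.0]))
        new, _ = step_cycle(state, matrix, mort, entrants, PathwayParams(),
                            cycle=5, initial_cohort=10_000.0)
        assert new.alive + new.cum_deaths == \
            pytest.approx(10_000.0 + entrants, abs=1e-6)


class TestRunHorizon:
    POPN = PopulationConfig()
    CLOSED = PopulationConfig(incidence_events=0, annual_mortality_risk=0.0)

    def matrix(self):
        sev = np.array([[0.899, 0.10, 0.0], [0.03, 0.913, 0.05], [0.0, 0.04, 0.944]])
        return TransitionMatrix(arm="soc", severity=sev,
                                p_aur=np.array([0.001, 0.004, 0.008]),
                                p_turp=np.array([0.0, 0.003, 0.008]))

    def test_zero_cycles_returns_initial(self):
        init = CohortState.from_split(1000.0, (0.07, 0.63, 0.30))
        res = run_horizon(init, self.matrix(), self.POPN, PathwayParams(), n_cycles=0)
        assert len(res.states) == 1 and res.states[0] is init

    def test_closed_cohort_total_constant(self):
        init = CohortState.from_split(10_000.0, (0.07, 0.63, 0.30))
        res = run_horizon(init, self.matrix(), self.CLOSED, PathwayParams())
        for s in res.states:
            assert s.alive == pytest.approx(10_000.0, abs=1e-6)

    def test_conservation_with_mortality_and_entrants(self):
        popn = PopulationConfig(annual_mortality_risk=0.02)
        init = CohortState.from_split(326_000.0, popn.initial_split)
        res = run_horizon(init, self.matrix(), popn, PathwayParams())
        final = res.states[-1]
        assert final.alive + final.cum_deaths == \
            pytest.approx(326_000.0 + final.cum_entrants, abs=1e-4)

    def test_death_and_post_surgery_absorbing(self):
        popn = PopulationConfig(incidence_events=0, annual_mortality_risk=0.02)
        init = CohortState.from_split(10_000.0, popn.initial_split)
        res = run_horizon(init, self.matrix(), popn, PathwayParams())
        deaths = [s.cum_deaths for s in res.states]
        assert all(a <= b + 1e-12 for a, b in zip(deaths, deaths[1:]))
        # post-surgery occupancy non-decreasing in a closed zero-mortality cohort
        res0 = run_horizon(CohortState.from_split(10_000.0, popn.initial_split),
                           self.matrix(), self.CLOSED, PathwayParams())
        ps = [s.post_surgery.total for s in res0.states]
        assert all(a <= b + 1e-9 for a, b in zip(ps, ps[1:]))

    def test_yearly_turps_decompose_into_sources(self):
        # tally-decomposition oracle: yearly TURPs = direct exits +
        # failed-TWOC conversions + second procedures, recomputed from the
        # raw per-cycle tallies
        init = CohortState.from_split(50_000.0, self.POPN.initial_split)
        res = run_horizon(init, self.matrix(), self.POPN,
                          PathwayParams(relapse_prob=0.01))
        ye = res.yearly_events()
        for year in ye:
            evs = [e for e in res.events if e.year == year]
            direct_plus_twoc = sum(e.first_turps for e in evs)
            second = sum(e.second_turps for e in evs)
            assert ye[year]["turps"] == pytest.approx(direct_plus_twoc + second)
            twoc_fail = sum(e.twoc_fail for e in evs)
            aur = sum(e.aur_episodes for e in evs)
            twoc_ok = sum(e.twoc_success for e in evs)
            assert twoc_fail + twoc_ok == pytest.approx(aur)
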