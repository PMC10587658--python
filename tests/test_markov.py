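"""Markov engine: transition matrices, cohort propagation, outcome accrual."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyp2c19_cea import (
    LifeTable,
    ParameterError,
    accumulate_outcomes,
    allocate_treatments,
    discount_factor,
    evaluate_strategy,
    run_cohort,
    run_subcohort,
    transition_matrix,
    with_value,
)
from cyp2c19_cea.markov import NO_STROKE, CohortTrace, STATES
from cyp2c19_cea.parameters import ParameterSet


def _flat_life_table(q: float, start: int = 67, end: int = 100) -> LifeTable:
    ages = np.arange(start, end + 1)
    qs = np.full(ages.shape, q, dtype=float)
    qs[-1] = 1.0
    return LifeTable(ages=ages, q=qs)


def _single_regimen_params(paper_params, p_first, p_after, fatal_fraction):
    """Clopidogrel with rr=1 so both genotype groups share p_first."""
    data = paper_params.model_dump()
    data["genetics"]["rr_clopidogrel_no_lof"] = 1.0
    data["risks"]["p_stroke_clopidogrel_avg"] = p_first
    data["risks"]["p_stroke_after_first_recurrence"] = p_after
    data["risks"]["fatal_stroke_fraction"] = fatal_fraction
    data["tolerance"]["clopidogrel"] = 1.0
    return ParameterSet.model_validate(data)


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "rate, t, expected",
        [(0.035, 0, 1.0), (0.035, 1, 1.0 / 1.035), (0.0, 17, 1.0)],
    )
    def test_closed_form(self, rate, t, expected):
        assert discount_factor(rate, t) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            discount_factor(0.035, -1)
        with pytest.raises(ParameterError):
            discount_factor(-0.01, 1)


class TestTransitionMatrix:
    def test_no_risk_no_mortality_is_identity(self):
        assert np.allclose(transition_matrix(0.0, 0.0, 0.2, 0.0), np.eye(5))

    def test_hand_arithmetic_from_no_stroke_state(self):
        m = transition_matrix(0.0279, 0.0, 0.2, 0.02)
        row = m[NO_STROKE]
        assert row[0] == pytest.approx(0.952658, abs=1e-9)   # stay
        assert row[1] == pytest.approx(0.022320, abs=1e-9)   # non-fatal recurrence
        assert row[3] == pytest.approx(0.005580, abs=1e-9)   # vascular death
        assert row[4] == pytest.approx(0.019442, abs=1e-9)   # non-vascular death

    def test_death_rows_absorbing_and_no_backward_moves(self):
        m = transition_matrix(0.1, 0.2, 0.3, 0.05)
        assert np.array_equal(m[3], np.eye(5)[3])
        assert np.array_equal(m[4], np.eye(5)[4])
        assert m[2, 0] == m[2, 1] == 0.0  # two-plus never de-escalates
        assert m[1, 0] == 0.0

    @given(
        p1=st.floats(0.0, 1.0),
        p2=st.floats(0.0, 1.0),
        f=st.floats(0.0, 1.0),
        q=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_rows_always_sum_to_one(self, p1, p2, f, q):
        m = transition_matrix(p1, p2, f, q)
        assert np.allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert np.all((m >= 0.0) & (m <= 1.0))


class TestCohortPropagation:
    def test_no_risks_means_nobody_moves(self, paper_params):
        params = _single_regimen_params(paper_params, 0.0, 0.0, 0.0)
        table = _flat_life_table(0.0)
        trace = run_subcohort(params, table, "no_lof", "clopidogrel")
        # all cycles before the horizon-closure cycle stay put
        assert np.all(trace.occupancy[:-1, NO_STROKE] == 1.0)

    def test_two_cycle_occupancy_equals_start_times_matrix_squared(self, paper_params):
        params = _single_regimen_params(paper_params, 0.08, 0.15, 0.25)
        table = _flat_life_table(0.03)
        trace = run_subcohort(params, table, "no_lof", "clopidogrel")
        m = transition_matrix(0.08, 0.15, 0.25, 0.03)
        start = np.eye(5)[0]
        expected = start @ m @ m
        assert np.allclose(trace.occupancy[2], expected, atol=1e-12)

    def test_cohort_extinct_at_horizon(self, paper_params, life_table):
        alloc = allocate_treatments("testing", paper_params)
        trace = run_cohort(alloc, paper_params, life_table)
        assert trace.alive[-1] == pytest.approx(0.0, abs=1e-15)

    def test_occupancy_conserved_and_alive_monotone(self, paper_params, life_table):
        alloc = allocate_treatments("no_testing", paper_params)
        trace = run_cohort(alloc, paper_params, life_table)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(np.diff(trace.alive) <= 1e-15)

    def test_aggregate_trace_is_allocation_weighted_sum(self, paper_params, life_table):
        alloc = allocate_treatments("testing", paper_params)
        agg = run_cohort(alloc, paper_params, life_table)
        manual = sum(
            w * run_subcohort(paper_params, life_table, g, r).occupancy
            for (g, r), w in alloc.fractions.items()
        )
        assert np.allclose(agg.occupancy, manual, atol=1e-15)

    def test_life_years_and_qalys_bounded(self, paper_params, life_table):
        alloc = allocate_treatments("testing", paper_params)
        trace = run_cohort(alloc, paper_params, life_table)
        life_years = trace.alive[:-1].sum()  # undiscounted person-years
        horizon = paper_params.cohort.max_age - paper_params.cohort.start_age + 1
        assert 0.0 < life_years <= horizon
        outcome = evaluate_strategy(alloc, paper_params, life_table)
        assert outcome.qalys <= life_years * paper_params.utilities.no_further_stroke


class TestOutcomeAccrual:
    def test_single_person_year_in_entry_state(self, paper_params):
        data = paper_params.model_dump()
        for r in ("clopidogrel", "mrd_aspirin", "aspirin"):
            data["costs"]["drug"][r] = 0.0
            data["costs"]["adverse_events"][r] = 0.0
            for ae in data["adverse_event_probabilities"][r]:
                data["adverse_event_probabilities"][r][ae] = 0.0
        params = ParameterSet.model_validate(data)
        occupancy = np.zeros((2, 5))
        occupancy[0, NO_STROKE] = 1.0
        occupancy[1, 4] = 1.0
        zeros = np.zeros(1)
        trace = CohortTrace(67, occupancy, zeros, zeros.copy(), zeros.copy())
        cost, qalys = accumulate_outcomes(trace, "clopidogrel", params)
        assert cost == pytest.approx(2087.0, abs=1e-12)
        assert qalys == pytest.approx(0.61, abs=1e-12)

    def test_stroke_state_utility_is_0436(self, paper_params):
        u = paper_params.utilities
        assert u.no_further_stroke - u.decrement_per_stroke_state == pytest.approx(
            0.436, abs=1e-12
        )

    def test_discounting_shrinks_totals(self, paper_params, life_table):
        alloc = allocate_treatments("no_testing", paper_params)
        undiscounted = with_value(paper_params, "p_stroke_clopidogrel_avg",
                                  paper_params.risks.p_stroke_clopidogrel_avg)
        data = undiscounted.model_dump()
        data["economics"]["discount_rate"] = 0.0
        params0 = ParameterSet.model_validate(data)
        out_d = evaluate_strategy(alloc, paper_params, life_table)
        out_0 = evaluate_strategy(allocate_treatments("no_testing", params0),
                                  params0, life_table)
        assert out_0.cost > out_d.cost
        assert out_0.qalys > out_d.qalys

    def test_trace_export_has_states_and_flows(self, paper_params, life_table):
        alloc = allocate_treatments("testing", paper_params)
        frame = run_cohort(alloc, paper_params, life_table).to_frame()
        for col in STATES:
            assert col in frame.columns
        assert {"cycle", "age", "new_nonfatal_strokes"} <= set(frame.columns)
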