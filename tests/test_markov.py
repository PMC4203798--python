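import dataclasses

import numpy as np
import pytest

from strokecea.markov import (
    REALLOCATION,
    recurrence_prob,
    reallocate_survivors,
    run_cohort,
    step,
)
from strokecea.decision_tree import ArmOutcome90d, pooled_arm_outcomes
from strokecea.mortality import build_life_table
from strokecea.params import ValidationError


# --- recurrence -----------------------------------------------------------

def test_recurrence_prob_examples(params):
    assert recurrence_prob(1, params) == pytest.approx(0.1181)
    assert recurrence_prob(5, params) == pytest.approx(0.1181 * 1.019**4, rel=1e-12)
    assert recurrence_prob(5, params) == pytest.approx(0.12735, abs=5e-5)


def test_recurrence_no_escalation(params):
    flat = dataclasses.replace(params, recur_rr_per_year=1.0)
    assert all(recurrence_prob(y, flat) == 0.1181 for y in range(1, 31))


def test_recurrence_capped_and_validated(params):
    hot = dataclasses.replace(params, recur_rate=0.9, recur_rr_per_year=1.5)
    assert recurrence_prob(20, hot) == 1.0
    with pytest.raises(ValidationError):
        recurrence_prob(0, params)


# --- survivor reallocation ------------------------------------------------

@pytest.mark.parametrize(
    "state,expected",
    [
        ("mrs01", (1 / 3, 1 / 3, 1 / 3)),
        ("mrs23", (0.0, 0.5, 0.5)),
        ("mrs45", (0.0, 0.0, 1.0)),
    ],
)
def test_reallocation_rows(state, expected):
    assert reallocate_survivors(state) == pytest.approx(expected)


def test_reallocation_rows_stochastic_and_dead_rejected():
    assert REALLOCATION.sum(axis=1) == pytest.approx((1, 1, 1))
    assert np.all(np.triu(REALLOCATION) >= 0) and np.all(np.tril(REALLOCATION, -1) == 0)
    with pytest.raises(ValidationError):
        reallocate_survivors("dead")
    with pytest.raises(ValidationError):
        reallocate_survivors(3)


# --- single step ----------------------------------------------------------

def test_step_dead_is_absorbing(params, life_table):
    occ, cost, qaly = step(np.array([0.0, 0, 0, 1.0]), 1, 64, "tpa", params, life_table)
    assert occ == pytest.approx((0, 0, 0, 1))
    assert cost == 0.0 and qaly == 0.0


def test_step_no_events_preserves_occupancy(params, zero_mortality_life_table):
    frozen = dataclasses.replace(params, recur_rate=0.0)
    occ0 = np.array([0.5, 0.3, 0.15, 0.05])
    occ, cost, qaly = step(occ0, 1, 64, "control", frozen, zero_mortality_life_table)
    assert occ == pytest.approx(occ0, abs=1e-15)
    assert qaly == pytest.approx(0.80 * 0.5 + 0.58 * 0.3 + 0.28 * 0.15, rel=1e-12)


def test_step_recurrence_splits_survivors(params, zero_mortality_life_table):
    occ, cost, qaly = step(
        np.array([1.0, 0, 0, 0]), 1, 64, "control", params, zero_mortality_life_table
    )
    dead = 0.1181 * 0.2101
    survivors = 0.1181 * (1 - 0.2101)
    assert occ[3] == pytest.approx(dead, abs=1e-5)
    assert occ[3] == pytest.approx(0.02481, abs=1e-5)
    assert occ[1] == pytest.approx(survivors / 3, rel=1e-9)
    assert occ[2] == pytest.approx(survivors / 3, rel=1e-9)
    assert occ[0] == pytest.approx(1 - 0.1181 + survivors / 3, rel=1e-9)


def test_step_mass_error(params, life_table):
    with pytest.raises(ValidationError):
        step(np.array([0.5, 0.2, 0.1, 0.1]), 1, 64, "tpa", params, life_table)


# --- cohort run -----------------------------------------------------------

def test_trace_conservation_and_monotonicity(windows, params, life_table, pooled):
    for arm in ("tpa", "control"):
        trace = run_cohort(arm, pooled[arm], params, life_table, 30)
        assert np.all(np.abs(trace.occupancy.sum(axis=1) - 1) < 1e-9)
        assert np.all(np.diff(trace.occupancy[:, 3]) >= -1e-12)
        assert np.all(np.diff(trace.cum_cost_disc) >= 0)
        assert np.all(np.diff(trace.cum_qaly_disc) >= 0)


def test_zero_discount_equals_independent_sum(params, life_table, pooled):
    """With 0% discounting, totals equal a manual undiscounted accumulation."""
    from strokecea.decision_tree import first_cycle_cost, first_cycle_qaly

    p0 = dataclasses.replace(params, disc_cost=0.0, disc_outcome=0.0)
    trace = run_cohort("tpa", pooled["tpa"], p0, life_table, 10)
    occ = pooled["tpa"].p
    cost = first_cycle_cost(pooled["tpa"], "tpa", p0)
    qaly = first_cycle_qaly(pooled["tpa"], p0)
    for y in range(1, 11):
        occ, c, q = step(occ, y, p0.start_age + y, "tpa", p0, life_table)
        cost += c
        qaly += q
    assert trace.cum_cost_disc[10] == pytest.approx(cost, rel=1e-12)
    assert trace.cum_qaly_disc[10] == pytest.approx(qaly, rel=1e-12)


def test_closed_form_when_nothing_happens(params, zero_mortality_life_table):
    """No deaths, no recurrence, utility 1, 0% discount: H + 0.25 QALYs."""
    frozen = dataclasses.replace(
        params,
        recur_rate=0.0, disc_cost=0.0, disc_outcome=0.0,
        utility_mrs01=1.0, utility_mrs23=1.0, utility_mrs45=1.0,
    )
    outcome = ArmOutcome90d(p=np.array([0.5, 0.3, 0.2, 0.0]), p_sich=0.0, arm="tpa")
    trace = run_cohort("tpa", outcome, frozen, zero_mortality_life_table, 12)
    for h in (1, 5, 12):
        _, qaly = trace.at_horizon(h)
        assert qaly == pytest.approx(0.25 + h, rel=1e-12)


@pytest.mark.parametrize("field,delta,direction", [
    ("utility_mrs23", +0.1, +1),
    ("utility_mrs45", +0.05, +1),
    ("recur_rate", +0.05, -1),
])
def test_qaly_dominance(windows, params, life_table, pooled, field, delta, direction):
    """More utility => more QALYs; more recurrence => fewer QALYs."""
    bumped = dataclasses.replace(params, **{field: getattr(params, field) + delta})
    base_q = run_cohort("tpa", pooled["tpa"], params, life_table, 30).cum_qaly_disc[-1]
    new_q = run_cohort("tpa", pooled["tpa"], bumped, life_table, 30).cum_qaly_disc[-1]
    assert direction * (new_q - base_q) > 0


def test_recurrence_increases_dead_fraction(params, life_table, pooled):
    hot = dataclasses.replace(params, recur_rate=0.2)
    base = run_cohort("tpa", pooled["tpa"], params, life_table, 30)
    more = run_cohort("tpa", pooled["tpa"], hot, life_table, 30)
    assert more.occupancy[-1, 3] > base.occupancy[-1, 3]


def test_accrual_conventions_differ_only_in_flows(params, life_table, pooled):
    start = run_cohort("tpa", pooled["tpa"], params, life_table, 30, accrual="start")
    end = run_cohort("tpa", pooled["tpa"], params, life_table, 30, accrual="end")
    assert start.occupancy == pytest.approx(end.occupancy, abs=1e-15)
    # start-of-cycle accrual counts people alive at cycle start, so flows
    # are weakly larger every cycle
    assert np.all(start.cycle_qaly_disc >= end.cycle_qaly_disc)
    assert start.cum_qaly_disc[-1] > end.cum_qaly_disc[-1]


def test_at_horizon_bounds(params, life_table, pooled):
    trace = run_cohort("tpa", pooled["tpa"], params, life_table, 5)
    with pytest.raises(ValidationError):
        trace.at_horizon(0)
    with pytest.raises(ValidationError):
        trace.at_horizon(6)
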