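"""Annual-cycle Markov cohort engine.

The cohort enters the Markov model in its 90-day state distribution
(cycle 0, spanning days 0-90) and then moves through annual cycles until
death or the 30-year horizon. Each annual cycle applies, in order:

1. recurrent stroke at the (escalating) annual recurrence probability,
   fatal with the recurrent-stroke case fatality; survivors are
   reallocated equally among states of equal or greater disability;
2. non-stroke death for the non-recurring mass, at the age-specific rate
   adjusted by the state's hazard ratio.

Recurrent-stroke survivors are not additionally exposed to non-stroke
death within the same cycle (the two causes act as sequential competing
events), and no half-cycle correction is applied. Annual cost and QALY
flows accrue on the start-of-cycle occupancy (transitions take effect at
cycle end), the accounting under which the published per-horizon results
are reproduced; end-of-cycle accrual is available as an option. Costs and
QALYs of cycle y are discounted by (1 + r)^-y; the 90-day cycle is
undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision_tree import ArmOutcome90d, first_cycle_cost, first_cycle_qaly
from .mortality import LifeTable, state_mortality
from .params import STATE_LABELS, ModelParams, ValidationError

__all__ = [
    "REALLOCATION",
    "CohortTrace",
    "recurrence_prob",
    "reallocate_survivors",
    "step",
    "run_cohort",
]

#: Row-stochastic reallocation of recurrent-stroke survivors: equal split
#: across the origin state and all more-disabled alive states.
REALLOCATION = np.array(
    [
        [1 / 3, 1 / 3, 1 / 3],
        [0.0, 1 / 2, 1 / 2],
        [0.0, 0.0, 1.0],
    ]
)


def recurrence_prob(year_index: int, params: ModelParams) -> float:
    """Annual stroke-recurrence probability for annual cycle ``year_index``.

    Base rate escalated ``recur_rr_per_year``-fold per elapsed life year,
    capped at 1.
    """
    if year_index < 1:
        raise ValidationError("year_index starts at 1 (first annual cycle)")
    return min(params.recur_rate * params.recur_rr_per_year ** (year_index - 1), 1.0)


def reallocate_survivors(from_state: int | str) -> np.ndarray:
    """Destination distribution of recurrent-stroke survivors from a state."""
    if isinstance(from_state, str):
        if from_state not in STATE_LABELS[:3]:
            raise ValidationError(f"no reallocation from state {from_state!r}")
        from_state = STATE_LABELS.index(from_state)
    if not 0 <= from_state <= 2:
        raise ValidationError("survivors can only be reallocated from an alive state")
    return REALLOCATION[from_state].copy()


def step(
    occ: np.ndarray,
    year_index: int,
    age: float,
    arm: str,
    params: ModelParams,
    life_table: LifeTable,
    accrual: str = "start",
) -> tuple[np.ndarray, float, float]:
    """One annual cycle: returns (new occupancy, cycle cost, cycle QALYs).

    Costs: alive occupancy (start-of-cycle by default, see module notes)
    priced at the annual post-hospitalization cost, plus one-time
    hospitalization for each expected recurrent event billed at the
    destination-state rate (deaths at the mRS 6 rate). QALYs: the same
    occupancy basis times state utility times one year. ``arm`` is part of
    the step contract but the annual flows are arm-independent (arms
    differ only at cycle 0).
    """
    if accrual not in ("start", "end"):
        raise ValidationError(f"unknown accrual convention {accrual!r}")
    occ = np.asarray(occ, dtype=float)
    if abs(occ.sum() - 1.0) > 1e-9:
        raise ValidationError(f"occupancy sums to {occ.sum():.12f}, not 1")
    r = recurrence_prob(year_index, params)
    f = params.recur_case_fatality
    q = life_table.q_at(age)

    alive = occ[:3]
    recur_deaths = alive * r * f
    recur_survivors = (alive * r * (1.0 - f)) @ REALLOCATION
    non_recurring = alive * (1.0 - r)
    q_state = np.array([state_mortality(q, hr) for hr in params.hazard_ratios])
    nonstroke_deaths = non_recurring * q_state
    new_alive = non_recurring - nonstroke_deaths + recur_survivors
    new_dead = occ[3] + recur_deaths.sum() + nonstroke_deaths.sum()
    new_occ = np.append(new_alive, new_dead)
    basis = alive if accrual == "start" else new_alive

    annual_cost = np.array(
        [params.cost_annual_mrs01, params.cost_annual_mrs25, params.cost_annual_mrs25]
    )
    hosp_dest = np.array(
        [params.cost_hosp_mrs01, params.cost_hosp_mrs25, params.cost_hosp_mrs25]
    )
    cycle_cost = (
        float(basis @ annual_cost)
        + float(recur_survivors @ hosp_dest)
        + recur_deaths.sum() * params.cost_hosp_mrs6
    )
    cycle_qaly = float(basis @ params.utilities[:3])
    return new_occ, cycle_cost, cycle_qaly


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle record of one arm's cohort run.

    Row 0 is the 90-day cycle; rows 1..H the annual cycles. ``cum_*`` are
    cumulative discounted sums through each cycle; :meth:`at_horizon`
    reads per-horizon totals off them.
    """

    arm: str
    occupancy: np.ndarray          # (H+1, 4)
    ages: np.ndarray               # (H+1,) cohort age at end of each cycle
    cycle_cost_disc: np.ndarray    # (H+1,)
    cycle_qaly_disc: np.ndarray    # (H+1,)
    cum_cost_disc: np.ndarray
    cum_qaly_disc: np.ndarray
    events: pd.DataFrame           # per-cycle expected recurrences / deaths

    @property
    def horizon_years(self) -> int:
        return len(self.cycle_cost_disc) - 1

    def at_horizon(self, horizon: int) -> tuple[float, float]:
        """(discounted cost, discounted QALYs) through ``horizon`` years.

        A horizon of H years counts the 90-day cycle plus annual cycles
        1..H in full — the convention under which the published
        per-horizon results (including the 1-year row) are reproduced.
        """
        if not 1 <= horizon <= self.horizon_years:
            raise ValidationError(
                f"horizon {horizon} outside run range 1..{self.horizon_years}"
            )
        return float(self.cum_cost_disc[horizon]), float(self.cum_qaly_disc[horizon])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATE_LABELS))
        df.insert(0, "cycle", np.arange(len(self.ages)))
        df.insert(1, "age", self.ages)
        df["cycle_cost_disc"] = self.cycle_cost_disc
        df["cycle_qaly_disc"] = self.cycle_qaly_disc
        df["cum_cost_disc"] = self.cum_cost_disc
        df["cum_qaly_disc"] = self.cum_qaly_disc
        return df

    def validate(self) -> None:
        sums = self.occupancy.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError("occupancy rows must sum to 1")
        dead = self.occupancy[:, 3]
        if np.any(np.diff(dead) < -1e-12):
            raise ValidationError("dead fraction must be non-decreasing")
        if np.any(np.diff(self.cum_cost_disc) < -1e-9) or np.any(
            np.diff(self.cum_qaly_disc) < -1e-12
        ):
            raise ValidationError("cumulative discounted totals must be non-decreasing")


def run_cohort(
    arm: str,
    outcome90: ArmOutcome90d,
    params: ModelParams,
    life_table: LifeTable,
    horizon_years: int | None = None,
    accrual: str = "start",
) -> CohortTrace:
    """Propagate one arm's cohort from its 90-day distribution to horizon.

    Cycle 0 (days 0-90): occupancy is the 90-day distribution, cost is the
    undiscounted index-hospitalization cost, QALYs are 0.25 years at the
    state utilities. Annual cycle y runs at cohort age start_age + y with
    discount factor (1 + r)^-y.
    """
    if horizon_years is None:
        horizon_years = params.horizon_years
    if horizon_years < 1:
        raise ValidationError("horizon_years must be >= 1")

    n = horizon_years + 1
    occupancy = np.zeros((n, 4))
    costs = np.zeros(n)
    qalys = np.zeros(n)
    ages = np.zeros(n)
    ev_recur = np.zeros(n)
    ev_recur_deaths = np.zeros(n)
    ev_nonstroke_deaths = np.zeros(n)

    occupancy[0] = outcome90.p
    ages[0] = params.start_age
    costs[0] = first_cycle_cost(outcome90, arm, params)
    qalys[0] = first_cycle_qaly(outcome90, params)

    occ = outcome90.p
    for y in range(1, horizon_years + 1):
        age = params.start_age + y
        alive_before = occ[:3].copy()
        r = recurrence_prob(y, params)
        occ, cost, qaly = step(occ, y, age, arm, params, life_table, accrual=accrual)
        occupancy[y] = occ
        ages[y] = age
        costs[y] = cost / (1.0 + params.disc_cost) ** y
        qalys[y] = qaly / (1.0 + params.disc_outcome) ** y
        ev_recur[y] = alive_before.sum() * r
        ev_recur_deaths[y] = alive_before.sum() * r * params.recur_case_fatality
        ev_nonstroke_deaths[y] = occ[3] - occupancy[y - 1][3] - ev_recur_deaths[y]

    events = pd.DataFrame(
        {
            "cycle": np.arange(n),
            "expected_recurrences": ev_recur,
            "expected_recurrent_deaths": ev_recur_deaths,
            "expected_nonstroke_deaths": ev_nonstroke_deaths,
        }
    )
    trace = CohortTrace(
        arm=arm,
        occupancy=occupancy,
        ages=ages,
        cycle_cost_disc=costs,
        cycle_qaly_disc=qalys,
        cum_cost_disc=np.cumsum(costs),
        cum_qaly_disc=np.cumsum(qalys),
        events=events,
    )
    trace.validate()
    return trace
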