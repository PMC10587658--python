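"""Five-state annual-cycle Markov cohort engine.

States: no additional stroke / one additional stroke / two or more
additional strokes / vascular death / non-vascular death.  The whole cohort
enters in ``no_additional_stroke`` (everyone has already had the index
stroke).  Each cycle a patient on regimen-specific recurrent-stroke risk
``p`` with case-fatality ``f`` either has a fatal recurrence (``p*f``), a
non-fatal recurrence (``p*(1-f)``, advancing the stroke count), or — if
stroke-free that cycle — dies of other causes with the life-table
probability ``q(age)``.  Death states are absorbing.

Competing risks are composed in that order (stroke resolved first,
background mortality applied to the stroke-free) as a stated convention.
The final cycle at the horizon age sets the stroke risk to zero and ``q`` to
one, so the cohort is fully extinct at the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    GROUPS,
    REGIMENS,
    InfeasibleParametersError,
    LifeTable,
    ParameterError,
    ParameterSet,
    derive_genotype_risks,
)
from .pathway import TreatmentAllocation

__all__ = [
    "STATES",
    "CohortTrace",
    "StrategyOutcome",
    "discount_factor",
    "stroke_risks",
    "transition_matrix",
    "build_transition_matrix",
    "run_subcohort",
    "run_cohort",
    "accumulate_outcomes",
    "evaluate_strategy",
]

STATES = (
    "no_additional_stroke",
    "one_additional_stroke",
    "two_plus_strokes",
    "vascular_death",
    "nonvascular_death",
)
NO_STROKE, ONE_STROKE, TWO_PLUS, VASC_DEATH, NONVASC_DEATH = range(5)
_LIVING = slice(0, 3)


def discount_factor(rate: float, t: int) -> float:
    """Annual discount factor ``(1 + rate)^-t`` applied to cycle ``t``."""
    if rate < 0.0:
        raise ParameterError("discount rate must be non-negative")
    if t < 0 or int(t) != t:
        raise ParameterError("cycle index must be a non-negative integer")
    return (1.0 + rate) ** (-int(t))


def stroke_risks(
    params: ParameterSet, group: str, regimen: str
) -> tuple[float, float]:
    """(first-recurrence, subsequent-recurrence) annual stroke probabilities
    for one (genotype group, regimen) sub-cohort.

    Clopidogrel risk is genotype-stratified via the mixture identity; the
    comparator drugs are genotype-independent.  The subsequent-recurrence
    risk is the baseline ``p_stroke_after_first_recurrence`` scaled by the
    sub-cohort's relative first-recurrence risk, so a treatment that lowers
    the first recurrence lowers later ones proportionally.
    """
    if group not in GROUPS:
        raise ParameterError(f"unknown genotype group {group!r}")
    if regimen not in REGIMENS:
        raise ParameterError(f"unknown regimen {regimen!r}")
    p_avg = params.risks.p_stroke_clopidogrel_avg
    if regimen == "clopidogrel":
        prev = params.genetics.lof_prevalence
        if 0.0 < prev < 1.0:
            p_no, p_lof = derive_genotype_risks(
                p_avg, params.genetics.rr_clopidogrel_no_lof, prev
            )
        else:
            # degenerate single-genotype population: no stratification
            p_no = p_lof = p_avg
        p_first = p_no if group == "no_lof" else p_lof
    elif regimen == "mrd_aspirin":
        p_first = params.risks.p_stroke_mrd_aspirin
    else:
        p_first = params.risks.p_stroke_aspirin

    rel = p_first / p_avg if p_avg > 0.0 else 1.0
    p_sub = params.risks.p_stroke_after_first_recurrence * rel
    if not 0.0 <= p_sub <= 1.0:
        raise InfeasibleParametersError(
            f"subsequent-stroke probability {p_sub:.6g} outside [0, 1] "
            f"for ({group}, {regimen})"
        )
    return p_first, p_sub


def transition_matrix(
    p_first: float, p_subsequent: float, fatal_fraction: float, q: float
) -> np.ndarray:
    """Assemble the 5x5 one-cycle transition matrix from annual risks.

    From a living state with recurrence risk ``p``: ``p*f`` to vascular
    death, ``p*(1-f)`` to the next stroke-count state (two-plus recurs into
    itself), ``(1-p)*q`` to non-vascular death, remainder stays.
    """
    for name, v in (
        ("p_first", p_first),
        ("p_subsequent", p_subsequent),
        ("fatal_fraction", fatal_fraction),
        ("q", q),
    ):
        if not 0.0 <= v <= 1.0:
            raise InfeasibleParametersError(f"{name}={v!r} outside [0, 1]")
    f = fatal_fraction
    m = np.zeros((5, 5))

    for state, p in ((NO_STROKE, p_first), (ONE_STROKE, p_subsequent)):
        m[state, VASC_DEATH] = p * f
        m[state, state + 1] = p * (1.0 - f)
        m[state, NONVASC_DEATH] = (1.0 - p) * q
        m[state, state] = 1.0 - p - (1.0 - p) * q
    p = p_subsequent
    m[TWO_PLUS, VASC_DEATH] = p * f
    m[TWO_PLUS, NONVASC_DEATH] = (1.0 - p) * q
    m[TWO_PLUS, TWO_PLUS] = 1.0 - p * f - (1.0 - p) * q  # non-fatal recurrences stay
    m[VASC_DEATH, VASC_DEATH] = 1.0
    m[NONVASC_DEATH, NONVASC_DEATH] = 1.0

    if np.any(m < -1e-15) or np.any(m > 1.0 + 1e-15):
        raise InfeasibleParametersError("transition matrix entry outside [0, 1]")
    np.clip(m, 0.0, 1.0, out=m)
    return m


def build_transition_matrix(
    params: ParameterSet,
    life_table: LifeTable,
    group: str,
    regimen: str,
    age: int,
) -> np.ndarray:
    """Age- and regimen-specific transition matrix for one sub-cohort."""
    p_first, p_sub = stroke_risks(params, group, regimen)
    return transition_matrix(
        p_first, p_sub, params.risks.fatal_stroke_fraction, life_table.q_at(age)
    )


@dataclass
class CohortTrace:
    """State occupancy per cycle plus the per-cycle event flows the costing
    needs (each non-fatal recurrence, fatal recurrence and non-stroke death
    triggers a one-off cost)."""

    start_age: int
    occupancy: np.ndarray  # (n_cycles + 1, 5)
    nonfatal_strokes: np.ndarray  # (n_cycles,)
    fatal_strokes: np.ndarray
    nonstroke_deaths: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def alive(self) -> np.ndarray:
        return self.occupancy[:, _LIVING].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        n = self.n_cycles
        frame = pd.DataFrame(self.occupancy, columns=list(STATES))
        frame.insert(0, "age", self.start_age + np.arange(n + 1))
        frame.insert(0, "cycle", np.arange(n + 1))
        for name, flow in (
            ("new_nonfatal_strokes", self.nonfatal_strokes),
            ("new_fatal_strokes", self.fatal_strokes),
            ("new_nonstroke_deaths", self.nonstroke_deaths),
        ):
            frame[name] = np.append(flow, np.nan)
        return frame


def run_subcohort(
    params: ParameterSet, life_table: LifeTable, group: str, regimen: str
) -> CohortTrace:
    """Propagate one (group, regimen) sub-cohort from start_age to max_age."""
    start, horizon = params.cohort.start_age, params.cohort.max_age
    if life_table.start_age > start or life_table.max_age < horizon:
        raise ParameterError("life table does not cover the model ages")
    n = horizon - start + 1
    p_first, p_sub = stroke_risks(params, group, regimen)
    f = params.risks.fatal_stroke_fraction

    occupancy = np.zeros((n + 1, 5))
    occupancy[0, NO_STROKE] = 1.0
    nonfatal = np.zeros(n)
    fatal = np.zeros(n)
    nonstroke = np.zeros(n)

    x = occupancy[0]
    for t in range(n):
        age = start + t
        if age == horizon:  # horizon closure: no further strokes modelled
            pf, ps, q = 0.0, 0.0, 1.0
        else:
            pf, ps, q = p_first, p_sub, life_table.q_at(age)
        m = transition_matrix(pf, ps, f, q)
        p_by_state = np.array([pf, ps, ps])
        living = x[_LIVING]
        nonfatal[t] = float(living @ (p_by_state * (1.0 - f)))
        fatal[t] = float(living @ (p_by_state * f))
        nonstroke[t] = float(living @ ((1.0 - p_by_state) * q))
        x = x @ m
        occupancy[t + 1] = x

    return CohortTrace(
        start_age=start,
        occupancy=occupancy,
        nonfatal_strokes=nonfatal,
        fatal_strokes=fatal,
        nonstroke_deaths=nonstroke,
    )


def run_cohort(
    allocation: TreatmentAllocation, params: ParameterSet, life_table: LifeTable
) -> CohortTrace:
    """Allocation-weighted aggregate trace across all sub-cohorts."""
    traces = [
        (w, run_subcohort(params, life_table, group, regimen))
        for (group, regimen), w in allocation.fractions.items()
        if w > 0.0
    ]
    first = traces[0][1]
    agg = CohortTrace(
        start_age=first.start_age,
        occupancy=sum(w * tr.occupancy for w, tr in traces),
        nonfatal_strokes=sum(w * tr.nonfatal_strokes for w, tr in traces),
        fatal_strokes=sum(w * tr.fatal_strokes for w, tr in traces),
        nonstroke_deaths=sum(w * tr.nonstroke_deaths for w, tr in traces),
    )
    return agg


def accumulate_outcomes(
    trace: CohortTrace, regimen: str, params: ParameterSet
) -> tuple[float, float]:
    """Discounted (cost, QALYs) per patient for a trace on one regimen.

    Each cycle the start-of-cycle occupancy accrues the state annual cost
    (non-disabling for the no-additional and one-additional states,
    disabling for two-plus), the regimen's annual drug and adverse-event
    treatment costs, and the state utility net of expected adverse-event
    disutility.  Event flows attract one-off costs, with non-fatal
    recurrences split disabling/non-disabling by ``disabling_fraction``.
    Optional half-cycle correction averages start- and end-of-cycle
    occupancy for the annual accruals.
    """
    if regimen not in REGIMENS:
        raise ParameterError(f"unknown regimen {regimen!r}")
    c, u = params.costs, params.utilities
    rate = params.economics.discount_rate
    df_dis = params.risks.disabling_fraction

    state_cost = np.array(
        [c.annual_nondisabling, c.annual_nondisabling, c.annual_disabling]
    )
    u_stroke = u.no_further_stroke - u.decrement_per_stroke_state
    state_utility = np.array([u.no_further_stroke, u_stroke, u_stroke])
    drug_cost = getattr(c.drug, regimen) + getattr(c.adverse_events, regimen)
    ae = getattr(params.adverse_event_probabilities, regimen)
    ae_disutility = (
        ae.minor_bleed * u.disutility_minor_bleed
        + ae.major_bleed * u.disutility_major_bleed
        + ae.chf * u.disutility_chf
    )
    one_off_nonfatal = (
        df_dis * c.one_off_disabling + (1.0 - df_dis) * c.one_off_nondisabling
    )

    total_cost = 0.0
    total_qaly = 0.0
    for t in range(trace.n_cycles):
        living = trace.occupancy[t, _LIVING]
        if params.options.half_cycle_correction:
            living = 0.5 * (living + trace.occupancy[t + 1, _LIVING])
        alive = living.sum()
        cycle_cost = float(living @ state_cost) + alive * drug_cost
        cycle_cost += (
            trace.nonfatal_strokes[t] * one_off_nonfatal
            + trace.fatal_strokes[t] * c.one_off_fatal_stroke
            + trace.nonstroke_deaths[t] * c.one_off_nonstroke_death
        )
        cycle_qaly = float(living @ state_utility) - alive * ae_disutility
        d = discount_factor(rate, t)
        total_cost += d * cycle_cost
        total_qaly += d * cycle_qaly
    return total_cost, total_qaly


@dataclass(frozen=True)
class StrategyOutcome:
    """Per-patient discounted totals for one strategy, with its aggregate
    trace kept for event counting and export."""

    strategy: str
    cost: float
    qalys: float
    trace: CohortTrace


def evaluate_strategy(
    allocation: TreatmentAllocation, params: ParameterSet, life_table: LifeTable
) -> StrategyOutcome:
    """Run every sub-cohort of an allocation, cost each on its own regimen,
    and aggregate by allocation weight.  The up-front testing cost enters
    undiscounted at cycle 0."""
    total_cost = allocation.upfront_cost_per_patient
    total_qalys = 0.0
    parts: list[tuple[float, CohortTrace]] = []
    for (group, regimen), w in allocation.fractions.items():
        if w <= 0.0:
            continue
        tr = run_subcohort(params, life_table, group, regimen)
        cost, qalys = accumulate_outcomes(tr, regimen, params)
        total_cost += w * cost
        total_qalys += w * qalys
        parts.append((w, tr))
    first = parts[0][1]
    agg = CohortTrace(
        start_age=first.start_age,
        occupancy=sum(w * tr.occupancy for w, tr in parts),
        nonfatal_strokes=sum(w * tr.nonfatal_strokes for w, tr in parts),
        fatal_strokes=sum(w * tr.fatal_strokes for w, tr in parts),
        nonstroke_deaths=sum(w * tr.nonstroke_deaths for w, tr in parts),
    )
    return StrategyOutcome(
        strategy=allocation.strategy, cost=total_cost, qalys=total_qalys, trace=agg
    )
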