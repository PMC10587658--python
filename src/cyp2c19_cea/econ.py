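"""Incremental economics: ICER, net benefit, dominance and population scaling.

Strategy ordering is fixed: subscript 2 = testing, 1 = no testing, so
``delta = testing - no_testing``.  With willingness to pay λ (GBP/QALY):

    ICER = ΔCost / ΔQALY            (labels cover the dominance quadrants)
    NHB  = ΔQALY - ΔCost / λ        (QALYs)
    NMB  = ΔQALY · λ - ΔCost        (GBP),  NMB = λ · NHB identically.

Display rounds GBP to the nearest pound and QALYs to three decimals; all
downstream arithmetic uses unrounded values.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import LifeTable, ParameterError, ParameterSet
from .pathway import allocate_treatments
from .markov import StrategyOutcome, evaluate_strategy

__all__ = [
    "icer",
    "nhb",
    "nmb",
    "scale_to_population",
    "EconResult",
    "run_base_case",
    "format_report",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
EQUIVALENT = "equivalent"


def icer(delta_cost: float, delta_qaly: float) -> float | str:
    """Incremental cost-effectiveness ratio, or a dominance label where the
    ratio is not meaningful."""
    if delta_cost == 0.0 and delta_qaly == 0.0:
        return EQUIVALENT
    if delta_cost <= 0.0 and delta_qaly >= 0.0:
        return DOMINANT
    if delta_cost >= 0.0 and delta_qaly <= 0.0:
        return DOMINATED
    return delta_cost / delta_qaly


def nhb(delta_qaly: float, delta_cost: float, lam: float) -> float:
    """Net health benefit, in QALYs."""
    if lam <= 0.0:
        raise ParameterError("lambda must be positive")
    return delta_qaly - delta_cost / lam


def nmb(delta_qaly: float, delta_cost: float, lam: float) -> float:
    """Net monetary benefit, in GBP."""
    if lam <= 0.0:
        raise ParameterError("lambda must be positive")
    return delta_qaly * lam - delta_cost


def scale_to_population(per_patient: float, n: int) -> float:
    """Population total from an unrounded per-patient quantity."""
    if n < 0:
        raise ParameterError("population size must be non-negative")
    return per_patient * n


@dataclass(frozen=True)
class EconResult:
    """Base-case incremental analysis of testing vs no testing."""

    cost_testing: float
    qalys_testing: float
    cost_no_testing: float
    qalys_no_testing: float
    delta_cost: float
    delta_qaly: float
    icer: float | str
    nhb_per_patient: float
    nmb_per_patient: float
    nhb_population: float
    nmb_population: float
    nonfatal_strokes_prevented: float
    fatal_strokes_prevented: float
    cohort_size: int
    lambda_per_qaly: float

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["display"] = {
            "cost_testing": round(self.cost_testing),
            "cost_no_testing": round(self.cost_no_testing),
            "qalys_testing": round(self.qalys_testing, 3),
            "qalys_no_testing": round(self.qalys_no_testing, 3),
            "delta_cost": round(self.delta_cost),
            "delta_qaly": round(self.delta_qaly, 3),
            "nhb_per_patient": round(self.nhb_per_patient, 3),
            "nmb_per_patient": round(self.nmb_per_patient),
            "nhb_population": round(self.nhb_population),
            "nmb_population": round(self.nmb_population),
        }
        d["units"] = {"money": "GBP 2021", "effect": "QALY"}
        return d


def run_base_case(params: ParameterSet, life_table: LifeTable) -> EconResult:
    """Full deterministic pipeline: decision tree, Markov cohorts, costing,
    incremental analysis and population scaling."""
    out_t: StrategyOutcome = evaluate_strategy(
        allocate_treatments("testing", params), params, life_table
    )
    out_nt: StrategyOutcome = evaluate_strategy(
        allocate_treatments("no_testing", params), params, life_table
    )
    dc = out_t.cost - out_nt.cost
    dq = out_t.qalys - out_nt.qalys
    lam = params.economics.lambda_per_qaly
    n = params.cohort.cohort_size
    nhb_pp = nhb(dq, dc, lam)
    nmb_pp = nmb(dq, dc, lam)
    return EconResult(
        cost_testing=out_t.cost,
        qalys_testing=out_t.qalys,
        cost_no_testing=out_nt.cost,
        qalys_no_testing=out_nt.qalys,
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer(dc, dq),
        nhb_per_patient=nhb_pp,
        nmb_per_patient=nmb_pp,
        nhb_population=scale_to_population(nhb_pp, n),
        nmb_population=scale_to_population(nmb_pp, n),
        nonfatal_strokes_prevented=scale_to_population(
            float(out_nt.trace.nonfatal_strokes.sum() - out_t.trace.nonfatal_strokes.sum()),
            n,
        ),
        fatal_strokes_prevented=scale_to_population(
            float(out_nt.trace.fatal_strokes.sum() - out_t.trace.fatal_strokes.sum()), n
        ),
        cohort_size=n,
        lambda_per_qaly=lam,
    )


def format_report(result: EconResult) -> str:
    """Human-readable summary mirroring a costs-and-consequences table."""
    icer_txt = (
        f"£{result.icer:,.0f}/QALY" if isinstance(result.icer, float) else result.icer
    )
    lines = [
        "Incremental cost-effectiveness of CYP2C19 testing vs no testing",
        f"  willingness to pay: £{result.lambda_per_qaly:,.0f}/QALY; "
        f"cohort: {result.cohort_size:,} patients",
        "",
        f"  {'strategy':<14}{'total cost (£)':>16}{'total QALYs':>14}",
        f"  {'testing':<14}{result.cost_testing:>16,.0f}{result.qalys_testing:>14.3f}",
        f"  {'no testing':<14}{result.cost_no_testing:>16,.0f}{result.qalys_no_testing:>14.3f}",
        "",
        f"  incremental cost:  £{result.delta_cost:,.0f}",
        f"  incremental QALYs: {result.delta_qaly:.3f}",
        f"  ICER:              {icer_txt}",
        f"  NHB per patient:   {result.nhb_per_patient:.3f} QALYs",
        f"  NMB per patient:   £{result.nmb_per_patient:,.0f}",
        f"  total NHB:         {result.nhb_population:,.0f} QALYs",
        f"  total NMB:         £{result.nmb_population:,.0f}",
        f"  non-fatal strokes prevented: {result.nonfatal_strokes_prevented:,.0f}",
        f"  fatal strokes prevented:     {result.fatal_strokes_prevented:,.0f}",
    ]
    return "\n".join(lines) + "\n"
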