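"""Decision-tree component: map a strategy to a treatment allocation.

The tree is resolved once at model entry.  Under testing, non-carriers get
clopidogrel first line (cascading to modified-release dipyridamole plus
aspirin, then aspirin alone, if not tolerated) while LoF carriers skip
clopidogrel and start on the dipyridamole cascade.  Without testing the
whole cohort enters the clopidogrel cascade regardless of genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .parameters import GROUPS, REGIMENS, ParameterSet

__all__ = ["STRATEGIES", "TreatmentAllocation", "allocate_treatments"]

STRATEGIES = ("testing", "no_testing")

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class TreatmentAllocation:
    """Fractions of the whole cohort in each (genotype group, regimen) cell,
    plus the per-patient up-front cost of the test itself."""

    strategy: str
    fractions: dict[tuple[str, str], float]
    upfront_cost_per_patient: float

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"allocation fractions sum to {total!r}, not 1")
        if any(f < 0.0 for f in self.fractions.values()):
            raise ValueError("allocation fractions must be non-negative")

    def fraction(self, group: str, regimen: str) -> float:
        return self.fractions.get((group, regimen), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"group": g, "regimen": r, "fraction": self.fraction(g, r)}
            for g in GROUPS
            for r in REGIMENS
        ]
        return pd.DataFrame(rows)


def _clopidogrel_cascade(tol_clop: float, tol_mrd: float) -> dict[str, float]:
    remainder = 1.0 - tol_clop
    return {
        "clopidogrel": tol_clop,
        "mrd_aspirin": remainder * tol_mrd,
        "aspirin": remainder * (1.0 - tol_mrd),
    }


def _mrd_cascade(tol_mrd: float) -> dict[str, float]:
    return {"mrd_aspirin": tol_mrd, "aspirin": 1.0 - tol_mrd}


def allocate_treatments(strategy: str, params: ParameterSet) -> TreatmentAllocation:
    """Resolve the decision tree for one strategy.

    Tolerance cascades: a patient intolerant of their first-line drug moves
    to the next option, so each group's regimen shares form a probability
    distribution.  A configurable test-failure fraction (default 0) falls
    back to the untested pathway.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")

    prev = params.genetics.lof_prevalence
    tol_c = params.tolerance.clopidogrel
    tol_m = params.tolerance.mrd_aspirin
    weights = {"no_lof": 1.0 - prev, "lof": prev}

    fractions: dict[tuple[str, str], float] = {}
    if strategy == "no_testing":
        cascade = _clopidogrel_cascade(tol_c, tol_m)
        for group, w in weights.items():
            for regimen, share in cascade.items():
                fractions[(group, regimen)] = w * share
        upfront = 0.0
    else:
        fail = params.options.test_failure_rate
        fallback = _clopidogrel_cascade(tol_c, tol_m)
        per_group = {
            "no_lof": _clopidogrel_cascade(tol_c, tol_m),
            "lof": _mrd_cascade(tol_m),
        }
        for group, w in weights.items():
            for regimen in REGIMENS:
                share = (1.0 - fail) * per_group[group].get(regimen, 0.0)
                share += fail * fallback.get(regimen, 0.0)
                fractions[(group, regimen)] = w * share
        upfront = params.costs.test + params.costs.staff

    fractions = {cell: f for cell, f in fractions.items() if f != 0.0}
    return TreatmentAllocation(
        strategy=strategy, fractions=fractions, upfront_cost_per_patient=upfront
    )
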