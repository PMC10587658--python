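"""Deterministic one-way threshold analysis.

For a registered scalar parameter, find the value at which the testing
strategy stops being cost-effective at the willingness-to-pay threshold.
The boundary is per-patient NMB = 0 (equivalent to ICER = λ in the
north-east quadrant, but also defined where the ICER is not).  The search
is plain bisection on the full pipeline, stopping when |NMB| falls below a
money tolerance; if NMB never changes sign on the bounds the result is
reported as no threshold in range.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import (
    SCALAR_PARAMETERS,
    LifeTable,
    ParameterError,
    ParameterSet,
    get_value,
    with_value,
)
from .econ import run_base_case

__all__ = ["ThresholdResult", "nmb_at", "threshold_search"]

DEFAULT_TOLERANCE = 0.01  # GBP per patient
DEFAULT_MAX_ITER = 200


@dataclass(frozen=True)
class ThresholdResult:
    parameter: str
    baseline: float
    lower: float
    upper: float
    threshold: float | None  # None => NMB keeps its sign on [lower, upper]
    nmb_at_threshold: float | None
    nmb_lower: float
    nmb_upper: float
    direction: str  # sign of dNMB/dparameter over the bounds
    n_evaluations: int

    @property
    def found(self) -> bool:
        return self.threshold is not None

    def describe(self) -> str:
        if not self.found:
            return (
                f"{self.parameter}: no threshold in [{self.lower:g}, {self.upper:g}] "
                f"(NMB stays {'positive' if self.nmb_lower > 0 else 'non-positive'})"
            )
        return (
            f"{self.parameter}: threshold {self.threshold:.6g} "
            f"(baseline {self.baseline:g}, NMB there £{self.nmb_at_threshold:.4f})"
        )


def nmb_at(
    param_name: str, value: float, params: ParameterSet, life_table: LifeTable
) -> float:
    """Per-patient NMB with one parameter moved, all else at base case."""
    return run_base_case(with_value(params, param_name, value), life_table).nmb_per_patient


def threshold_search(
    param_name: str,
    bounds: tuple[float, float],
    params: ParameterSet,
    life_table: LifeTable,
    tolerance: float = DEFAULT_TOLERANCE,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ThresholdResult:
    """Bisection for the parameter value where per-patient NMB crosses zero."""
    if param_name not in SCALAR_PARAMETERS:
        raise ParameterError(
            f"unknown parameter {param_name!r}; registered: "
            f"{', '.join(sorted(SCALAR_PARAMETERS))}"
        )
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise ParameterError(f"invalid bounds ({lo!r}, {hi!r}): need lower < upper")

    baseline = get_value(params, param_name)
    g_lo = nmb_at(param_name, lo, params, life_table)
    g_hi = nmb_at(param_name, hi, params, life_table)
    evaluations = 2
    direction = "decreasing" if g_hi < g_lo else "increasing"

    def result(threshold, nmb_thr):
        return ThresholdResult(
            parameter=param_name,
            baseline=baseline,
            lower=lo,
            upper=hi,
            threshold=threshold,
            nmb_at_threshold=nmb_thr,
            nmb_lower=g_lo,
            nmb_upper=g_hi,
            direction=direction,
            n_evaluations=evaluations,
        )

    for endpoint, g in ((lo, g_lo), (hi, g_hi)):
        if abs(g) <= tolerance:
            return result(endpoint, g)
    if (g_lo > 0.0) == (g_hi > 0.0):
        return result(None, None)

    a, ga, b = lo, g_lo, hi
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        g_mid = nmb_at(param_name, mid, params, life_table)
        evaluations += 1
        if abs(g_mid) <= tolerance:
            return result(mid, g_mid)
        if (g_mid > 0.0) == (ga > 0.0):
            a, ga = mid, g_mid
        else:
            b = mid
    mid = 0.5 * (a + b)
    g_mid = nmb_at(param_name, mid, params, life_table)
    evaluations += 1
    return result(mid, g_mid)
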