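"""Model inputs: validated parameter sets, life tables and derived quantities.

The decision model compares two prescribing strategies after a first
ischaemic, non-cardioembolic stroke:

* ``testing`` — a point-of-care *CYP2C19* genotype test; carriers of a
  loss-of-function (LoF) allele are steered away from clopidogrel towards
  modified-release dipyridamole plus aspirin (or aspirin alone).
* ``no_testing`` — universal clopidogrel first line.

All inputs live in a single :class:`ParameterSet`, loaded from a versioned
YAML file.  Values the source appraisal does not publish (secondary-stroke
risks on the comparator drugs, case-fatality of recurrence, drug tolerance,
adverse-event probabilities) are explicit, documented assumptions in the
default fixture and can be overridden without code changes.

Monetary values are GBP at 2021 prices throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "REGIMENS",
    "GROUPS",
    "SCHEMA_VERSION",
    "ParameterError",
    "InfeasibleParametersError",
    "ParameterSet",
    "LifeTable",
    "CohortCounts",
    "load_parameters",
    "save_parameters",
    "estimate_population",
    "derive_genotype_risks",
    "generate_life_table",
    "load_life_table",
    "save_life_table",
    "SCALAR_PARAMETERS",
    "get_value",
    "with_value",
]

#: Antiplatelet regimens a patient can end up on.
REGIMENS = ("clopidogrel", "mrd_aspirin", "aspirin")

#: Genotype groups: carriers of >=1 CYP2C19 loss-of-function allele vs none.
GROUPS = ("no_lof", "lof")

SCHEMA_VERSION = 1


class ParameterError(ValueError):
    """A model input is missing, malformed or outside its support."""


class InfeasibleParametersError(ParameterError):
    """Inputs are individually valid but jointly imply an impossible model
    (e.g. a derived probability outside [0, 1])."""


# --------------------------------------------------------------------------
# Parameter schema
# --------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


Probability = Field(ge=0.0, le=1.0)
Money = Field(ge=0.0)


class Cohort(_Strict):
    """Who enters the model and for how long it runs."""

    start_age: int = Field(ge=0, description="mean age at the index stroke, years")
    max_age: int = Field(ge=1, description="model horizon: run until this age")
    cohort_size: int = Field(ge=0, description="annual UK first ischaemic strokes")

    @model_validator(mode="after")
    def _ordered(self) -> "Cohort":
        if self.start_age >= self.max_age:
            raise ValueError("start_age must be below max_age")
        return self


class Genetics(_Strict):
    lof_prevalence: float = Probability
    rr_clopidogrel_no_lof: float = Field(
        gt=0.0,
        description="recurrent-stroke risk ratio, non-carriers on clopidogrel "
        "vs the unstratified clopidogrel population",
    )


class Risks(_Strict):
    """Annual event probabilities in the Markov component."""

    p_stroke_clopidogrel_avg: float = Probability
    p_stroke_mrd_aspirin: float = Probability
    p_stroke_aspirin: float = Probability
    p_stroke_after_first_recurrence: float = Probability
    fatal_stroke_fraction: float = Probability
    disabling_fraction: float = Probability


class Tolerance(_Strict):
    """Fraction of patients able to remain on each drug (cascade resolved
    once at model entry)."""

    clopidogrel: float = Probability
    mrd_aspirin: float = Probability


class RegimenValues(_Strict):
    clopidogrel: float = Money
    mrd_aspirin: float = Money
    aspirin: float = Money


class Costs(_Strict):
    test: float = Money
    staff: float = Money
    annual_nondisabling: float = Money
    annual_disabling: float = Money
    one_off_nondisabling: float = Money
    one_off_disabling: float = Money
    one_off_fatal_stroke: float = Money
    one_off_nonstroke_death: float = Money
    drug: RegimenValues
    adverse_events: RegimenValues


class Utilities(_Strict):
    no_further_stroke: float = Probability
    decrement_per_stroke_state: float = Probability
    disutility_minor_bleed: float = Probability
    disutility_major_bleed: float = Probability
    disutility_chf: float = Probability

    @model_validator(mode="after")
    def _nonnegative_stroke_state(self) -> "Utilities":
        if self.decrement_per_stroke_state > self.no_further_stroke:
            raise ValueError(
                "decrement_per_stroke_state exceeds no_further_stroke utility"
            )
        return self


class AeProbabilities(_Strict):
    minor_bleed: float = Probability
    major_bleed: float = Probability
    chf: float = Probability


class AdverseEventProbabilities(_Strict):
    clopidogrel: AeProbabilities
    mrd_aspirin: AeProbabilities
    aspirin: AeProbabilities


class Economics(_Strict):
    discount_rate: float = Field(ge=0.0, description="annual, costs and QALYs")
    lambda_per_qaly: float = Field(gt=0.0, description="willingness to pay, GBP/QALY")


class Options(_Strict):
    half_cycle_correction: bool = False
    test_failure_rate: float = Probability  # hook; 0 in all shipped fixtures


class PsaOverride(_Strict):
    family: Literal["beta", "gamma", "lognormal", "fixed"]
    dispersion: float = Field(ge=0.0, description="standard error of the draw")


class PsaSettings(_Strict):
    cost_cv: float = Field(default=0.15, ge=0.0)
    probability_se_scale: float = Field(default=0.10, ge=0.0)
    ratio_cv: float = Field(default=0.10, ge=0.0)
    overrides: dict[str, PsaOverride] = Field(default_factory=dict)


class ParameterSet(_Strict):
    """Every input the pipeline needs, validated on construction."""

    schema_version: Literal[1] = SCHEMA_VERSION
    cohort: Cohort
    genetics: Genetics
    risks: Risks
    tolerance: Tolerance
    costs: Costs
    utilities: Utilities
    adverse_event_probabilities: AdverseEventProbabilities
    economics: Economics
    options: Options = Field(default_factory=lambda: Options(test_failure_rate=0.0))
    psa: PsaSettings = Field(default_factory=PsaSettings)

    @model_validator(mode="after")
    def _jointly_feasible(self) -> "ParameterSet":
        # the genotype-stratified risks must exist for the stated mixture
        if 0.0 < self.genetics.lof_prevalence < 1.0:
            derive_genotype_risks(
                self.risks.p_stroke_clopidogrel_avg,
                self.genetics.rr_clopidogrel_no_lof,
                self.genetics.lof_prevalence,
            )
        return self


# --------------------------------------------------------------------------
# Scalar-parameter registry (threshold analysis, PSA sampling)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamInfo:
    path: tuple[str, ...]
    kind: Literal["probability", "cost", "ratio", "utility"]


def _regimen_entries(prefix: str, *path: str, kind: str) -> dict[str, ParamInfo]:
    return {
        f"{prefix}_{r}": ParamInfo(tuple(path) + (r,), kind)  # type: ignore[arg-type]
        for r in REGIMENS
    }


SCALAR_PARAMETERS: dict[str, ParamInfo] = {
    "lof_prevalence": ParamInfo(("genetics", "lof_prevalence"), "probability"),
    "rr_clopidogrel_no_lof": ParamInfo(("genetics", "rr_clopidogrel_no_lof"), "ratio"),
    "p_stroke_clopidogrel_avg": ParamInfo(("risks", "p_stroke_clopidogrel_avg"), "probability"),
    "p_stroke_mrd_aspirin": ParamInfo(("risks", "p_stroke_mrd_aspirin"), "probability"),
    "p_stroke_aspirin": ParamInfo(("risks", "p_stroke_aspirin"), "probability"),
    "p_stroke_after_first_recurrence": ParamInfo(
        ("risks", "p_stroke_after_first_recurrence"), "probability"
    ),
    "fatal_stroke_fraction": ParamInfo(("risks", "fatal_stroke_fraction"), "probability"),
    "disabling_fraction": ParamInfo(("risks", "disabling_fraction"), "probability"),
    "tolerance_clopidogrel": ParamInfo(("tolerance", "clopidogrel"), "probability"),
    "tolerance_mrd_aspirin": ParamInfo(("tolerance", "mrd_aspirin"), "probability"),
    "test_cost": ParamInfo(("costs", "test"), "cost"),
    "staff_cost": ParamInfo(("costs", "staff"), "cost"),
    "annual_cost_nondisabling": ParamInfo(("costs", "annual_nondisabling"), "cost"),
    "annual_cost_disabling": ParamInfo(("costs", "annual_disabling"), "cost"),
    "one_off_cost_nondisabling": ParamInfo(("costs", "one_off_nondisabling"), "cost"),
    "one_off_cost_disabling": ParamInfo(("costs", "one_off_disabling"), "cost"),
    "one_off_cost_fatal_stroke": ParamInfo(("costs", "one_off_fatal_stroke"), "cost"),
    "one_off_cost_nonstroke_death": ParamInfo(("costs", "one_off_nonstroke_death"), "cost"),
    **_regimen_entries("drug_cost", "costs", "drug", kind="cost"),
    **_regimen_entries("ae_cost", "costs", "adverse_events", kind="cost"),
    "utility_no_further_stroke": ParamInfo(("utilities", "no_further_stroke"), "utility"),
    "utility_decrement_per_stroke_state": ParamInfo(
        ("utilities", "decrement_per_stroke_state"), "utility"
    ),
    "disutility_minor_bleed": ParamInfo(("utilities", "disutility_minor_bleed"), "utility"),
    "disutility_major_bleed": ParamInfo(("utilities", "disutility_major_bleed"), "utility"),
    "disutility_chf": ParamInfo(("utilities", "disutility_chf"), "utility"),
    **{
        f"p_{ae}_{r}": ParamInfo(("adverse_event_probabilities", r, ae), "probability")
        for r in REGIMENS
        for ae in ("minor_bleed", "major_bleed", "chf")
    },
}


def get_value(params: ParameterSet, name: str) -> float:
    """Read a registered scalar parameter by name."""
    info = SCALAR_PARAMETERS.get(name)
    if info is None:
        raise ParameterError(
            f"unknown parameter {name!r}; registered: {', '.join(sorted(SCALAR_PARAMETERS))}"
        )
    obj: object = params
    for key in info.path:
        obj = getattr(obj, key)
    return float(obj)  # type: ignore[arg-type]


def with_value(params: ParameterSet, name: str, value: float) -> ParameterSet:
    """Return a new, fully revalidated ParameterSet with one scalar changed."""
    info = SCALAR_PARAMETERS.get(name)
    if info is None:
        raise ParameterError(
            f"unknown parameter {name!r}; registered: {', '.join(sorted(SCALAR_PARAMETERS))}"
        )
    data = params.model_dump()
    node = data
    for key in info.path[:-1]:
        node = node[key]
    node[info.path[-1]] = value
    try:
        return ParameterSet.model_validate(data)
    except ValidationError as exc:
        raise ParameterError(str(exc)) from exc


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------

def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a parameter YAML file.

    Raises :class:`ParameterError` naming the offending field on validation
    failure, or ``yaml.YAMLError`` on a malformed file.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ParameterError(f"{path}: expected a mapping at top level")
    try:
        return ParameterSet.model_validate(raw)
    except ValidationError as exc:
        raise ParameterError(f"{path}: {exc}") from exc


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.model_dump(), fh, sort_keys=False)


# --------------------------------------------------------------------------
# Population derivation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortCounts:
    first_strokes: int
    ischaemic_strokes: int


def estimate_population(
    incidence_per_1000: float, population: float, ischaemic_fraction: float
) -> CohortCounts:
    """Annual first strokes, and the ischaemic subset, in a population.

    ``first_strokes = round(incidence/1000 * population)``;
    ``ischaemic_strokes = round(ischaemic_fraction * first_strokes)``.
    With the UK inputs (1.07 per 1,000; 66,436,000; 85% ischaemic) this gives
    71,087 first strokes and a modelled cohort of 60,424.
    """
    if incidence_per_1000 < 0 or population < 0:
        raise ParameterError("incidence and population must be non-negative")
    if not 0.0 <= ischaemic_fraction <= 1.0:
        raise ParameterError("ischaemic_fraction must lie in [0, 1]")
    first = int(round(incidence_per_1000 / 1000.0 * population))
    ischaemic = int(round(ischaemic_fraction * first))
    return CohortCounts(first_strokes=first, ischaemic_strokes=ischaemic)


# --------------------------------------------------------------------------
# Genotype-stratified risks
# --------------------------------------------------------------------------

def derive_genotype_risks(
    p_avg: float, rr_no_lof: float, f_lof: float
) -> tuple[float, float]:
    """Split the unstratified clopidogrel stroke risk by genotype.

    The population risk is the prevalence-weighted mean of the two genotype
    groups, so given the non-carrier risk ratio ``rr_no_lof`` the carrier
    risk is fixed by the mixture identity::

        (1 - f_lof) * p_no_lof + f_lof * p_lof = p_avg

    Returns ``(p_no_lof, p_lof)``.
    """
    if not 0.0 < f_lof < 1.0:
        raise ParameterError("f_lof must lie strictly inside (0, 1)")
    if rr_no_lof <= 0.0:
        raise ParameterError("rr_no_lof must be positive")
    if not 0.0 <= p_avg <= 1.0:
        raise ParameterError("p_avg must be a probability")
    p_no_lof = rr_no_lof * p_avg
    p_lof = p_avg * (1.0 - (1.0 - f_lof) * rr_no_lof) / f_lof
    if not (0.0 <= p_no_lof <= 1.0 and 0.0 <= p_lof <= 1.0):
        raise InfeasibleParametersError(
            f"derived genotype risks outside [0, 1]: "
            f"p_no_lof={p_no_lof:.6g}, p_lof={p_lof:.6g}"
        )
    return p_no_lof, p_lof


# --------------------------------------------------------------------------
# Life tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Annual probability of death from causes other than the modelled
    vascular deaths, indexed by integer age.

    The final age closes the table with q = 1 so the cohort cannot outlive
    the horizon.
    """

    ages: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "q", q)
        if ages.ndim != 1 or ages.shape != q.shape or ages.size == 0:
            raise ParameterError("life table needs matching 1-D age and q columns")
        if not np.all(np.diff(ages) == 1):
            raise ParameterError("life table ages must be consecutive integers")
        if np.any((q < 0.0) | (q > 1.0)):
            raise ParameterError("life table q values must lie in [0, 1]")
        if q[-1] != 1.0:
            raise ParameterError("life table must close with q = 1 at the final age")

    @property
    def start_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q_at(self, age: int) -> float:
        if not self.start_age <= age <= self.max_age:
            raise ParameterError(
                f"age {age} outside life table range "
                f"[{self.start_age}, {self.max_age}]"
            )
        return float(self.q[age - self.start_age])


def generate_life_table(
    a: float, b: float, start_age: int, max_age: int
) -> LifeTable:
    """Synthetic Gompertz life table: hazard ``a * exp(b * age)``, so
    ``q(age) = 1 - exp(-a * exp(b * age))``, clipped to 1 and forced to 1 at
    ``max_age``. Deterministic given its inputs."""
    if a <= 0.0 or b <= 0.0:
        raise ParameterError("Gompertz parameters a and b must be positive")
    if start_age >= max_age:
        raise ParameterError("start_age must be below max_age")
    ages = np.arange(start_age, max_age + 1)
    q = np.minimum(1.0, 1.0 - np.exp(-a * np.exp(b * ages)))
    q[-1] = 1.0
    return LifeTable(ages=ages, q=q)


def load_life_table(path: str | Path) -> LifeTable:
    """Read a two-column delimited text file (header ``age<TAB>q``)."""
    import pandas as pd

    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ("," if "," in header else r"\s+")
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    cols = [c.strip().lower() for c in frame.columns]
    if "age" not in cols or "q" not in cols:
        raise ParameterError(f"{path}: expected columns 'age' and 'q'")
    frame.columns = cols
    return LifeTable(
        ages=frame["age"].to_numpy(dtype=int), q=frame["q"].to_numpy(dtype=float)
    )


def save_life_table(table: LifeTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("age\tq\n")
        for age, q in zip(table.ages, table.q):
            fh.write(f"{int(age)}\t{float(q)!r}\n")
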