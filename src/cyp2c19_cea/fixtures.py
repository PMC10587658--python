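"""Synthetic, internally consistent model inputs.

No machine-readable inputs are deposited with the source appraisal, so this
module generates them: a complete parameter file built around the published
point estimates (test cost £60, staff time £16.91, unit costs, utilities
0.61 / 0.436, adverse-event disutilities, LoF prevalence 25%, risk ratio
0.702, λ £20,000/QALY, 3.5% discounting, start age 67, cohort 60,424) with
documented assumptions for the inputs the appraisal does not print, and a
synthetic Gompertz life table standing in for national mortality data.

Scenarios
---------
``paper_default``
    The base case described above.
``null_effect``
    Risk ratio 1 and identical risks/costs across regimens: testing buys
    nothing, so the incremental result must be exactly the up-front test
    cost and zero QALYs — a sharp end-to-end oracle.
``extreme_effect``
    Risk ratio 0.3: a large, directionally unambiguous benefit.
``randomized``
    Seeded uniform draws within each parameter's support, for property
    testing.  Deterministic per seed.

Assumed (unpublished) inputs live under the ``assumptions`` comment block of
the emitted YAML so sourcing real values later is a data edit, not a code
change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .parameters import (
    LifeTable,
    ParameterError,
    ParameterSet,
    generate_life_table,
    save_life_table,
    with_value,
)

__all__ = [
    "SCENARIOS",
    "GOMPERTZ_A",
    "GOMPERTZ_B",
    "FixtureSpec",
    "paper_default_parameters",
    "null_effect_parameters",
    "extreme_effect_parameters",
    "randomized_parameters",
    "scenario_parameters",
    "default_life_table",
    "generate_fixture",
]

SCENARIOS = ("paper_default", "null_effect", "extreme_effect", "randomized")

# Gompertz hazard a*exp(b*age), calibrated so annual all-cause mortality is
# roughly 1.3% at 67 and 12% at 90 — plausible for a UK cohort at these ages.
GOMPERTZ_A = 2.0e-5
GOMPERTZ_B = 0.097


@dataclass(frozen=True)
class FixtureSpec:
    scenario: str = "paper_default"
    seed: int | None = None
    overrides: dict[str, float] = field(default_factory=dict)


def paper_default_parameters() -> ParameterSet:
    """Base-case inputs: published point estimates plus documented
    assumptions for the unprinted transition and tolerance inputs."""
    data = {
        "schema_version": 1,
        "cohort": {"start_age": 67, "max_age": 100, "cohort_size": 60424},
        "genetics": {"lof_prevalence": 0.25, "rr_clopidogrel_no_lof": 0.702},
        "risks": {
            # p_avg chosen so the stratified non-carrier risk is 2.79%/yr
            "p_stroke_clopidogrel_avg": 0.03974,
            # assumption: comparator drugs match unstratified clopidogrel
            "p_stroke_mrd_aspirin": 0.03974,
            "p_stroke_aspirin": 0.03974,
            # assumption: elevated risk once a recurrence has occurred
            "p_stroke_after_first_recurrence": 0.06,
            # assumption: one in five recurrences immediately fatal
            "fatal_stroke_fraction": 0.20,
            # assumption: even split of non-fatal recurrences by disability
            "disabling_fraction": 0.50,
        },
        # assumption: tolerance shares (threshold analysis varies these)
        "tolerance": {"clopidogrel": 0.95, "mrd_aspirin": 0.90},
        "costs": {
            "test": 60.0,
            "staff": 16.91,
            "annual_nondisabling": 2087.0,
            "annual_disabling": 6407.0,
            "one_off_nondisabling": 7936.0,
            "one_off_disabling": 16896.0,
            "one_off_fatal_stroke": 10855.0,
            "one_off_nonstroke_death": 2755.0,
            "drug": {"clopidogrel": 32.0, "mrd_aspirin": 82.0, "aspirin": 22.0},
            "adverse_events": {"clopidogrel": 25.0, "mrd_aspirin": 32.0, "aspirin": 27.0},
        },
        "utilities": {
            "no_further_stroke": 0.61,
            "decrement_per_stroke_state": 0.174,
            "disutility_minor_bleed": 0.0033,
            "disutility_major_bleed": 0.1426,
            "disutility_chf": 0.0163,
        },
        # assumption: annual adverse-event probabilities per regimen
        "adverse_event_probabilities": {
            "clopidogrel": {"minor_bleed": 0.030, "major_bleed": 0.010, "chf": 0.005},
            "mrd_aspirin": {"minor_bleed": 0.035, "major_bleed": 0.008, "chf": 0.008},
            "aspirin": {"minor_bleed": 0.030, "major_bleed": 0.010, "chf": 0.004},
        },
        "economics": {"discount_rate": 0.035, "lambda_per_qaly": 20000.0},
        "options": {"half_cycle_correction": False, "test_failure_rate": 0.0},
        "psa": {"cost_cv": 0.15, "probability_se_scale": 0.10, "ratio_cv": 0.10},
    }
    return ParameterSet.model_validate(data)


def null_effect_parameters() -> ParameterSet:
    """No treatment effect and interchangeable regimens: the only difference
    between the arms is the up-front test cost."""
    base = paper_default_parameters().model_dump()
    base["genetics"]["rr_clopidogrel_no_lof"] = 1.0
    p = base["risks"]["p_stroke_clopidogrel_avg"]
    base["risks"]["p_stroke_mrd_aspirin"] = p
    base["risks"]["p_stroke_aspirin"] = p
    for block in ("drug", "adverse_events"):
        v = base["costs"][block]["clopidogrel"]
        base["costs"][block] = {r: v for r in ("clopidogrel", "mrd_aspirin", "aspirin")}
    ae = base["adverse_event_probabilities"]["clopidogrel"]
    base["adverse_event_probabilities"] = {
        r: dict(ae) for r in ("clopidogrel", "mrd_aspirin", "aspirin")
    }
    return ParameterSet.model_validate(base)


def extreme_effect_parameters() -> ParameterSet:
    """Implausibly strong stratified benefit (risk ratio 0.3)."""
    return with_value(paper_default_parameters(), "rr_clopidogrel_no_lof", 0.3)


def randomized_parameters(seed: int) -> ParameterSet:
    """Uniform draws within each parameter's support; retried until the
    joint draw is feasible.  Deterministic per seed."""
    rng = np.random.default_rng(seed)
    for _ in range(200):
        u = float(rng.uniform(0.40, 0.85))
        data = {
            "schema_version": 1,
            "cohort": {"start_age": 67, "max_age": 100, "cohort_size": 60424},
            "genetics": {
                "lof_prevalence": float(rng.uniform(0.10, 0.40)),
                "rr_clopidogrel_no_lof": float(rng.uniform(0.50, 1.10)),
            },
            "risks": {
                "p_stroke_clopidogrel_avg": float(rng.uniform(0.01, 0.08)),
                "p_stroke_mrd_aspirin": float(rng.uniform(0.01, 0.08)),
                "p_stroke_aspirin": float(rng.uniform(0.01, 0.08)),
                "p_stroke_after_first_recurrence": float(rng.uniform(0.02, 0.12)),
                "fatal_stroke_fraction": float(rng.uniform(0.05, 0.40)),
                "disabling_fraction": float(rng.uniform(0.20, 0.80)),
            },
            "tolerance": {
                "clopidogrel": float(rng.uniform(0.50, 1.00)),
                "mrd_aspirin": float(rng.uniform(0.50, 1.00)),
            },
            "costs": {
                "test": float(rng.uniform(20.0, 200.0)),
                "staff": float(rng.uniform(5.0, 50.0)),
                "annual_nondisabling": float(rng.uniform(1000.0, 4000.0)),
                "annual_disabling": float(rng.uniform(4000.0, 10000.0)),
                "one_off_nondisabling": float(rng.uniform(4000.0, 12000.0)),
                "one_off_disabling": float(rng.uniform(10000.0, 25000.0)),
                "one_off_fatal_stroke": float(rng.uniform(5000.0, 18000.0)),
                "one_off_nonstroke_death": float(rng.uniform(1000.0, 5000.0)),
                "drug": {
                    "clopidogrel": float(rng.uniform(10.0, 120.0)),
                    "mrd_aspirin": float(rng.uniform(10.0, 120.0)),
                    "aspirin": float(rng.uniform(10.0, 120.0)),
                },
                "adverse_events": {
                    "clopidogrel": float(rng.uniform(5.0, 60.0)),
                    "mrd_aspirin": float(rng.uniform(5.0, 60.0)),
                    "aspirin": float(rng.uniform(5.0, 60.0)),
                },
            },
            "utilities": {
                "no_further_stroke": u,
                "decrement_per_stroke_state": float(rng.uniform(0.05, 0.5 * u)),
                "disutility_minor_bleed": float(rng.uniform(0.0, 0.02)),
                "disutility_major_bleed": float(rng.uniform(0.02, 0.25)),
                "disutility_chf": float(rng.uniform(0.0, 0.05)),
            },
            "adverse_event_probabilities": {
                r: {
                    "minor_bleed": float(rng.uniform(0.0, 0.06)),
                    "major_bleed": float(rng.uniform(0.0, 0.03)),
                    "chf": float(rng.uniform(0.0, 0.02)),
                }
                for r in ("clopidogrel", "mrd_aspirin", "aspirin")
            },
            "economics": {
                "discount_rate": float(rng.uniform(0.0, 0.05)),
                "lambda_per_qaly": 20000.0,
            },
            "options": {"half_cycle_correction": False, "test_failure_rate": 0.0},
            "psa": {"cost_cv": 0.15, "probability_se_scale": 0.10, "ratio_cv": 0.10},
        }
        try:
            return ParameterSet.model_validate(data)
        except Exception:
            continue  # infeasible joint draw; redraw
    raise ParameterError(f"could not draw a feasible random parameter set (seed {seed})")


def scenario_parameters(spec: FixtureSpec) -> ParameterSet:
    if spec.scenario not in SCENARIOS:
        raise ParameterError(
            f"unknown scenario {spec.scenario!r}; expected one of {SCENARIOS}"
        )
    if spec.scenario == "paper_default":
        params = paper_default_parameters()
    elif spec.scenario == "null_effect":
        params = null_effect_parameters()
    elif spec.scenario == "extreme_effect":
        params = extreme_effect_parameters()
    else:
        if spec.seed is None:
            raise ParameterError("randomized scenario requires a seed")
        params = randomized_parameters(spec.seed)
    for name, value in spec.overrides.items():
        params = with_value(params, name, value)
    return params


def default_life_table(start_age: int = 67, max_age: int = 100) -> LifeTable:
    return generate_life_table(GOMPERTZ_A, GOMPERTZ_B, start_age, max_age)


def generate_fixture(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a parameter YAML and life-table TSV for a scenario; returns
    their paths.  Deterministic per (scenario, seed, overrides)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = scenario_parameters(spec)
    params_path = out / "parameters.yaml"
    with open(params_path, "w") as fh:
        fh.write(f"# scenario: {spec.scenario}")
        fh.write(f" (seed {spec.seed})\n" if spec.seed is not None else "\n")
        fh.write(
            "# Unpublished inputs (comparator stroke risks, recurrence risk,\n"
            "# fatal fraction, tolerances, adverse-event probabilities,\n"
            "# disabling split) are package assumptions - see docs/methods.md.\n"
        )
        yaml.safe_dump(params.model_dump(), fh, sort_keys=False)
    table = default_life_table(params.cohort.start_age, params.cohort.max_age)
    table_path = out / "life_table.tsv"
    save_life_table(table, table_path)
    return params_path, table_path
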