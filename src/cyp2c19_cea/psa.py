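"""Probabilistic sensitivity analysis.

Each iteration redraws every uncertain parameter from its assigned
distribution (method-of-moments fits around the point estimate), reruns the
whole decision-tree + Markov pipeline, and records the incremental pair.
Families follow the usual convention for decision models: beta for
probabilities, proportions and utilities; gamma for costs; lognormal for
risk ratios.  Default dispersions (SE = 0.10 x mean for beta-like inputs,
CV 0.15 for costs, CV 0.10 for the risk ratio) are package assumptions and
can be overridden per parameter in the parameter file.

One master seed drives independent per-iteration substreams
(``numpy.random.SeedSequence.spawn``), so results are reproducible and
invariant to execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    SCALAR_PARAMETERS,
    InfeasibleParametersError,
    LifeTable,
    ParameterError,
    ParameterSet,
    get_value,
)
from . import econ

__all__ = [
    "DistributionSpec",
    "PsaResult",
    "default_specs",
    "beta_moments",
    "gamma_moments",
    "lognormal_moments",
    "sample_parameters",
    "run_psa",
    "ceac",
]

_MAX_RETRIES = 100


@dataclass(frozen=True)
class DistributionSpec:
    """One uncertain parameter: family plus (point, standard error)."""

    name: str
    family: str  # beta | gamma | lognormal | fixed
    point: float
    se: float

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "lognormal", "fixed"):
            raise ParameterError(f"unknown distribution family {self.family!r}")
        if self.se < 0.0:
            raise ParameterError("standard error must be non-negative")


def beta_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta(alpha, beta) for a given mean and SE."""
    if not 0.0 < mean < 1.0:
        raise ParameterError("beta mean must lie strictly inside (0, 1)")
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ParameterError(
            f"beta SE {se:.4g} too large for mean {mean:.4g} "
            "(variance must be below mean*(1-mean))"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_moments(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma (shape, scale)."""
    if mean <= 0.0:
        raise ParameterError("gamma mean must be positive")
    shape = (mean / se) ** 2
    return shape, mean / shape


def lognormal_moments(mean: float, se: float) -> tuple[float, float]:
    """(mu, sigma) of log X matching an arithmetic mean and SE."""
    if mean <= 0.0:
        raise ParameterError("lognormal mean must be positive")
    sigma2 = math.log(1.0 + (se / mean) ** 2)
    return math.log(mean) - 0.5 * sigma2, math.sqrt(sigma2)


def default_specs(params: ParameterSet) -> dict[str, DistributionSpec]:
    """Distribution for every registered scalar, from the PSA settings block.

    Parameters at the edge of their support (probability 0 or 1, cost 0) are
    held fixed — there is no uncertainty to spread without leaving the
    support.  Explicit overrides in ``params.psa.overrides`` win.
    """
    specs: dict[str, DistributionSpec] = {}
    cfg = params.psa
    for name, info in SCALAR_PARAMETERS.items():
        point = get_value(params, name)
        if name in cfg.overrides:
            ov = cfg.overrides[name]
            specs[name] = DistributionSpec(name, ov.family, point, ov.dispersion)
            continue
        if info.kind in ("probability", "utility"):
            se = cfg.probability_se_scale * point
            family = "beta" if 0.0 < point < 1.0 and se > 0.0 else "fixed"
        elif info.kind == "cost":
            se = cfg.cost_cv * point
            family = "gamma" if point > 0.0 and se > 0.0 else "fixed"
        else:  # ratio
            se = cfg.ratio_cv * point
            family = "lognormal" if point > 0.0 and se > 0.0 else "fixed"
        specs[name] = DistributionSpec(name, family, point, se)
    return specs


def _draw(spec: DistributionSpec, rng: np.random.Generator) -> float:
    if spec.family == "fixed" or spec.se == 0.0:
        return spec.point
    if spec.family == "beta":
        a, b = beta_moments(spec.point, spec.se)
        return float(rng.beta(a, b))
    if spec.family == "gamma":
        shape, scale = gamma_moments(spec.point, spec.se)
        return float(rng.gamma(shape, scale))
    mu, sigma = lognormal_moments(spec.point, spec.se)
    return float(rng.lognormal(mu, sigma))


def sample_parameters(
    params: ParameterSet,
    specs: dict[str, DistributionSpec],
    rng: np.random.Generator,
) -> ParameterSet:
    """One joint draw of all uncertain parameters, revalidated as a full
    ParameterSet.  Raises :class:`InfeasibleParametersError` (via
    validation) when a draw is jointly impossible; callers may resample."""
    data = params.model_dump()
    for name, spec in specs.items():
        info = SCALAR_PARAMETERS[name]
        node = data
        for key in info.path[:-1]:
            node = node[key]
        node[info.path[-1]] = _draw(spec, rng)
    try:
        return ParameterSet.model_validate(data)
    except InfeasibleParametersError:
        raise
    except Exception as exc:  # pydantic range violations -> infeasible draw
        raise InfeasibleParametersError(str(exc)) from exc


@dataclass
class PsaResult:
    """Per-iteration incremental pairs plus plane summaries."""

    n_iterations: int
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    nhb: np.ndarray
    nmb: np.ndarray
    mean_cost_testing: float
    mean_qalys_testing: float
    mean_cost_no_testing: float
    mean_qalys_no_testing: float
    lambda_per_qaly: float
    n_resampled: int = 0

    @property
    def p_cost_effective(self) -> float:
        """Proportion of iterations with strictly positive net benefit."""
        return float(np.mean(self.nmb > 0.0))

    @property
    def p_cost_saving(self) -> float:
        """Proportion of iterations where testing costs strictly less."""
        return float(np.mean(self.delta_cost < 0.0))

    def to_plane_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iterations),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
                "nhb": self.nhb,
                "nmb": self.nmb,
            }
        )

    def summary(self) -> dict:
        return {
            "n_iterations": self.n_iterations,
            "mean_delta_cost": float(np.mean(self.delta_cost)),
            "mean_delta_qaly": float(np.mean(self.delta_qaly)),
            "mean_cost_testing": self.mean_cost_testing,
            "mean_qalys_testing": self.mean_qalys_testing,
            "mean_cost_no_testing": self.mean_cost_no_testing,
            "mean_qalys_no_testing": self.mean_qalys_no_testing,
            "mean_nhb": float(np.mean(self.nhb)),
            "mean_nmb": float(np.mean(self.nmb)),
            "p_cost_effective": self.p_cost_effective,
            "p_cost_saving": self.p_cost_saving,
            "lambda_per_qaly": self.lambda_per_qaly,
            "n_resampled": self.n_resampled,
        }


def run_psa(
    params: ParameterSet,
    life_table: LifeTable,
    n_iterations: int,
    seed: int,
    specs: dict[str, DistributionSpec] | None = None,
) -> PsaResult:
    """Re-run the full pipeline ``n_iterations`` times under parameter
    uncertainty.  Infeasible joint draws are resampled from the same
    substream (capped at 100 per iteration) and counted."""
    if n_iterations < 1:
        raise ParameterError("n_iterations must be at least 1")
    if specs is None:
        specs = default_specs(params)

    streams = np.random.SeedSequence(seed).spawn(n_iterations)
    dc = np.empty(n_iterations)
    dq = np.empty(n_iterations)
    cost_t = np.empty(n_iterations)
    qaly_t = np.empty(n_iterations)
    cost_nt = np.empty(n_iterations)
    qaly_nt = np.empty(n_iterations)
    lam = params.economics.lambda_per_qaly
    resampled = 0

    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        for attempt in range(_MAX_RETRIES + 1):
            try:
                draw = sample_parameters(params, specs, rng)
                result = econ.run_base_case(draw, life_table)
                break
            except InfeasibleParametersError:
                resampled += 1
                if attempt == _MAX_RETRIES:
                    raise ParameterError(
                        f"iteration {i}: exceeded {_MAX_RETRIES} resampling attempts"
                    )
        dc[i] = result.delta_cost
        dq[i] = result.delta_qaly
        cost_t[i] = result.cost_testing
        qaly_t[i] = result.qalys_testing
        cost_nt[i] = result.cost_no_testing
        qaly_nt[i] = result.qalys_no_testing

    return PsaResult(
        n_iterations=n_iterations,
        delta_cost=dc,
        delta_qaly=dq,
        nhb=dq - dc / lam,
        nmb=dq * lam - dc,
        mean_cost_testing=float(cost_t.mean()),
        mean_qalys_testing=float(qaly_t.mean()),
        mean_cost_no_testing=float(cost_nt.mean()),
        mean_qalys_no_testing=float(qaly_nt.mean()),
        lambda_per_qaly=lam,
        n_resampled=resampled,
    )


def ceac(result: PsaResult, lambda_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: for each willingness to pay,
    the proportion of iterations with positive net monetary benefit."""
    grid = np.asarray(lambda_grid, dtype=float)
    if grid.size == 0:
        raise ParameterError("lambda grid must be non-empty")
    if np.any(grid <= 0.0):
        raise ParameterError("lambda grid values must be positive")
    prob = [
        float(np.mean(result.delta_qaly * lam - result.delta_cost > 0.0))
        for lam in grid
    ]
    return pd.DataFrame({"lambda": grid, "p_cost_effective": prob})


def plot_plane(result: PsaResult, path) -> None:
    """Scatter of the incremental cost-effectiveness plane (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(result.delta_qaly, result.delta_cost, s=6, alpha=0.4)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axvline(0.0, color="grey", lw=0.8)
    lam = result.lambda_per_qaly
    xs = np.array(ax.get_xlim())
    ax.plot(xs, lam * xs, color="firebrick", lw=0.8, label=f"λ = £{lam:,.0f}/QALY")
    ax.set_xlabel("incremental QALYs per patient")
    ax.set_ylabel("incremental cost per patient (£)")
    ax.set_title("Cost-effectiveness plane")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
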