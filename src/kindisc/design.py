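"""Discriminatory-experiment design: wire models, divergences and GDE3.

A :class:`DesignProblem` holds two or more fully parameterized candidate
models, the initial concentrations to optimize (decision variables with box
bounds), the fixed conditions, the observable species, and the equidistant
time grid on which predictions are compared.  :func:`run_design` maximizes
all directed extended Kullback-Leibler distances between the candidates'
predicted time courses simultaneously with GDE3 and reports the Pareto
front of initial-condition designs.

The shipped glyoxalase problem optimizes the initial GSH and MGO
concentrations in [0, 1] mM with both enzymes fixed (glyoxalase I at
2.0e-3 mM, glyoxalase II at 4.0e-4 mM) on a 0-120 min grid, observing only
SDLGS (followed spectrophotometrically at 240 nm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import divergence as dv
from .errors import SimulationError
from .estimation import Dataset, ssq_objective
from .gde3 import GDE3Result, GDE3Settings, Solution, gde3_run
from .models import (
    DEFAULT_ENZYMES,
    KineticModel,
    TimeCourse,
    TimeGrid,
    build_glyoxalase_model,
    simulate,
)

__all__ = [
    "DesignProblem",
    "DesignResult",
    "ModelScores",
    "evaluate_design",
    "run_design",
    "landscape_scan",
    "score_models",
    "absorbance_to_concentration",
    "glyoxalase_design_problem",
    "ABSORPTION_COEFFICIENT_SDLGS",
]

logger = logging.getLogger(__name__)

#: Molar absorption coefficient of SDLGS at 240 nm (mM^-1 cm^-1).
ABSORPTION_COEFFICIENT_SDLGS = 2.86

#: Metrics available to :func:`landscape_scan` (two-model problems):
#: directed KL in both directions plus the two L2 comparison norms.
LANDSCAPE_METRICS = ("I12", "I21", "L2", "L2w")


@dataclass(frozen=True)
class DesignProblem:
    """A model-discrimination design problem.

    ``decision_variables`` are species whose initial concentrations are
    optimized inside ``bounds`` (mM, shape (d, 2)); ``fixed`` completes the
    initial state.  All candidate models must share the species set.
    """

    models: tuple[KineticModel, ...]
    decision_variables: tuple[str, ...]
    bounds: np.ndarray
    fixed: Mapping[str, float]
    observables: tuple[str, ...]
    grid: TimeGrid
    eps: float = dv.DEFAULT_EPS
    rtol: float = 1e-8
    atol: float = 1e-12

    def __post_init__(self):
        object.__setattr__(self, "bounds", np.asarray(self.bounds, dtype=float))
        if len(self.models) < 2:
            raise ValueError("need at least two candidate models")
        species = set(self.models[0].species)
        for m in self.models[1:]:
            if set(m.species) != species:
                raise ValueError("candidate models must share species names")
        dec, fix = set(self.decision_variables), set(self.fixed)
        if dec & fix:
            raise ValueError("decision and fixed species overlap")
        if dec | fix != species:
            raise ValueError("decision + fixed must cover every dynamic species")
        if self.bounds.shape != (len(self.decision_variables), 2):
            raise ValueError("bounds shape must be (n_decision_vars, 2)")
        if np.any(~np.isfinite(self.bounds)) or np.any(self.bounds[:, 0] < 0):
            raise ValueError("bounds must be finite with non-negative lower bounds")
        if not self.observables:
            raise ValueError("observable set must be non-empty")

    def assemble_ic(self, point: Sequence[float]) -> dict[str, float]:
        ic = dict(self.fixed)
        ic.update(zip(self.decision_variables, map(float, point)))
        return ic


@dataclass
class DesignResult:
    """Pareto-front designs plus the underlying optimizer output.

    Front solutions are ordered by descending objective sum; ``time_courses``
    holds, per front solution, the predicted time course of each candidate
    model at that solution's initial conditions.
    """

    problem: DesignProblem
    front: list[Solution]
    optimizer: GDE3Result
    settings: GDE3Settings
    seed: int | None
    time_courses: list[tuple[TimeCourse, ...]] = field(default_factory=list)

    def front_decisions(self) -> np.ndarray:
        return np.array([s.decision for s in self.front])

    def front_objectives(self) -> np.ndarray:
        return np.array([s.objectives for s in self.front])


def _simulate_all(problem: DesignProblem, ic) -> tuple[TimeCourse, ...]:
    return tuple(
        simulate(m, ic, problem.grid, rtol=problem.rtol, atol=problem.atol)
        for m in problem.models
    )


def evaluate_design(point: Sequence[float], problem: DesignProblem) -> np.ndarray:
    """Objective vector (all directed KL distances) at one design point.

    A simulation failure yields the all-zero vector (the worst possible
    value under maximization) and a log record, so the optimizer can move on.
    """
    k = len(problem.models)
    ic = problem.assemble_ic(point)
    try:
        courses = _simulate_all(problem, ic)
    except SimulationError as exc:
        logger.warning("simulation failed at design point %s: %s", point, exc)
        return np.zeros(k * (k - 1))
    return dv.pairwise_objectives(courses, problem.observables, problem.eps)


def run_design(problem: DesignProblem, settings: GDE3Settings) -> DesignResult:
    """Optimize the design problem with GDE3 and report the Pareto front."""
    result = gde3_run(
        lambda x: evaluate_design(x, problem), problem.bounds, settings
    )
    front = sorted(
        result.front, key=lambda s: -float(np.sum(s.objectives))
    )
    courses = [
        _simulate_all(problem, problem.assemble_ic(s.decision)) for s in front
    ]
    return DesignResult(
        problem=problem,
        front=front,
        optimizer=result,
        settings=settings,
        seed=settings.seed,
        time_courses=courses,
    )


def landscape_scan(
    problem: DesignProblem,
    metrics: str | Sequence[str] = LANDSCAPE_METRICS,
    resolution: int = 50,
):
    """Evaluate divergence metrics on a regular lattice over a 2-D design box.

    Only defined for exactly two decision variables and two candidate
    models.  Returns ``(axes, values)`` where ``axes`` is a pair of
    1-D arrays (lattice coordinates per decision variable, bounds included)
    and ``values`` maps each requested metric to a (resolution, resolution)
    array indexed [i, j] = (first variable, second variable).
    """
    if len(problem.decision_variables) != 2:
        raise ValueError("landscape scan requires exactly two decision variables")
    if len(problem.models) != 2:
        raise ValueError("landscape metrics are defined for two models")
    if isinstance(metrics, str):
        metrics = (metrics,)
    unknown = set(metrics) - set(LANDSCAPE_METRICS)
    if unknown:
        raise ValueError(f"unknown metrics {sorted(unknown)}")
    axes = (
        np.linspace(*problem.bounds[0], resolution),
        np.linspace(*problem.bounds[1], resolution),
    )
    values = {m: np.full((resolution, resolution), np.nan) for m in metrics}
    obs = problem.observables
    for i, a in enumerate(axes[0]):
        for j, b in enumerate(axes[1]):
            try:
                f1, f2 = _simulate_all(problem, problem.assemble_ic((a, b)))
            except SimulationError:
                continue
            for m in metrics:
                if m == "I12":
                    values[m][i, j] = dv.kl_extended(f1, f2, obs, problem.eps)
                elif m == "I21":
                    values[m][i, j] = dv.kl_extended(f2, f1, obs, problem.eps)
                elif m == "L2":
                    values[m][i, j] = dv.l2_simple(f1, f2, obs)
                else:
                    try:
                        values[m][i, j] = dv.l2_weighted(f1, f2, obs)
                    except Exception:
                        values[m][i, j] = np.nan
    return axes, values


@dataclass
class ModelScores:
    """Per-model SSQ against one dataset, with residuals and a ranking."""

    ssq: dict[str, float]
    ranking: list[str]
    residuals: dict[str, list[np.ndarray]]


def score_models(data: Dataset, models: Sequence[KineticModel]) -> ModelScores:
    """Score candidate models (at fixed parameters) against measured data.

    Lower SSQ is better; ``ranking`` lists model names best-first.  With an
    empty dataset all scores are zero and no ranking is produced.
    """
    from .estimation import predict

    ssq: dict[str, float] = {}
    residuals: dict[str, list[np.ndarray]] = {}
    for i, m in enumerate(models):
        key = m.name if m.name not in ssq else f"{m.name}#{i}"
        ssq[key] = ssq_objective({}, m, data)
        res = []
        for exp in data:
            try:
                res.append(exp.values - predict(m, exp))
            except SimulationError:
                res.append(np.full_like(exp.values, np.nan))
        residuals[key] = res
    ranking = [] if len(data) == 0 else sorted(ssq, key=ssq.get)
    return ModelScores(ssq=ssq, ranking=ranking, residuals=residuals)


def absorbance_to_concentration(a240: float, path_cm: float = 1.0) -> float:
    """Convert SDLGS absorbance at 240 nm to concentration (mM).

    Beer-Lambert with the 2.86 mM^-1 cm^-1 absorption coefficient.
    """
    if a240 < 0:
        raise ValueError("absorbance must be non-negative")
    if path_cm <= 0:
        raise ValueError("path length must be positive")
    return a240 / (ABSORPTION_COEFFICIENT_SDLGS * path_cm)


def glyoxalase_design_problem(
    enzymes: Mapping[str, float] | None = None,
    substrate_bound: float = 1.0,
    grid: TimeGrid | None = None,
) -> DesignProblem:
    """The shipped two-model glyoxalase discrimination problem.

    Decision variables: initial GSH and MGO in [0, ``substrate_bound``] mM;
    HTA and SDLGS start at zero; both enzymes fixed (defaults 2.0e-3 and
    4.0e-4 mM); observable SDLGS on a 0-120 min grid with 121 points.
    """
    e = dict(DEFAULT_ENZYMES)
    if enzymes:
        e.update(enzymes)
    return DesignProblem(
        models=(build_glyoxalase_model(1, enzymes=e), build_glyoxalase_model(2, enzymes=e)),
        decision_variables=("GSH", "MGO"),
        bounds=np.array([[0.0, substrate_bound], [0.0, substrate_bound]]),
        fixed={"HTA": 0.0, "SDLGS": 0.0},
        observables=("SDLGS",),
        grid=grid or TimeGrid(0.0, 1.0, 121),
    )
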