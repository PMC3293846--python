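"""Collective least-squares parameter estimation with Fisher-information errors.

Kinetic parameters are fitted simultaneously to several time courses (a
*collective fit*): each experiment has its own initial conditions and
possibly its own enzyme concentrations, while the kinetic parameters are
shared.  The non-weighted objective is

    SSQ(P) = sum_i sum_j ( X_exp,ij - X_pred,ij(P) )^2        [mM^2]

minimized globally with differential evolution (DE/rand/1/bin, CR = 0.7,
F = 0.5) and refined with the deterministic Nelder-Mead downhill simplex.
Kinetic constants span orders of magnitude, so the search runs in log10
parameter space; reported values and errors are on the natural scale.

Standard errors are Cramér-Rao lower bounds: the square roots of the
diagonal of the inverse Fisher information matrix

    F = sum over measured points  S^T V^-1 S,

where S is the dynamic parameter-sensitivity matrix obtained by extending
the model ODEs with dS/dt = (df/dx) S + df/dp (Jacobians derived
symbolically with sympy) and V is the (diagonal) measurement-error
covariance.  Large standard errors with preserved predictive power —
*sloppiness* — are common in time-course collective fits; an
ill-conditioned information matrix triggers a warning instead of errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import odeint
from scipy.optimize import differential_evolution, minimize

from .errors import (
    EstimationFailureError,
    SimulationError,
    SloppinessWarning,
)
from .models import (
    MASS_ACTION_REVERSIBLE,
    MM_IRREV_1S,
    KineticModel,
)

__all__ = [
    "Experiment",
    "Dataset",
    "ParameterEstimate",
    "EstimationSettings",
    "PENALTY_SSQ",
    "ssq_objective",
    "fit_collective",
    "sensitivity_system",
    "integrate_sensitivities",
    "fisher_information",
    "standard_errors",
]

#: Sentinel objective value returned when a simulation fails, so that DE can
#: continue past infeasible parameter vectors.
PENALTY_SSQ = 1e15

#: Condition-number threshold above which the FIM is reported as sloppy.
SLOPPINESS_CONDITION = 1e12


@dataclass(frozen=True)
class Experiment:
    """One measured time course.

    ``initial_conditions`` covers the dynamic species (mM);
    ``constants`` optionally overrides enzyme concentrations for this
    experiment.  ``values`` has shape (len(observed), len(times)).
    """

    initial_conditions: Mapping[str, float]
    observed: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray
    constants: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if v.shape != (len(self.observed), len(t)):
            raise ValueError(
                f"values shape {v.shape} inconsistent with "
                f"{len(self.observed)} observables x {len(t)} times"
            )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass
class Dataset:
    """A collection of experiments entering one collective fit."""

    experiments: list[Experiment]

    def __iter__(self):
        return iter(self.experiments)

    def __len__(self):
        return len(self.experiments)


@dataclass
class ParameterEstimate:
    """Fitted parameter values, Cramér-Rao standard errors and the FIM.

    ``standard_errors`` is None when the information matrix is too
    ill-conditioned to invert reliably.
    """

    values: dict[str, float]
    standard_errors: dict[str, float] | None
    fim: np.ndarray | None
    objective_value: float
    sigma: float


@dataclass(frozen=True)
class EstimationSettings:
    """Fitting configuration.

    ``bounds`` maps each *free* parameter to (lower, upper) on the natural
    scale; the default bounds bracket typical enzyme constants by at least
    two orders of magnitude: kcat in [1e2, 1e7] min^-1, Km in [1e-3, 1e2]
    mM.  ``sigma`` (mM) fixes the diagonal measurement-error covariance;
    when None it is estimated as the RMS residual at the optimum.
    """

    bounds: Mapping[str, tuple[float, float]]
    de_popsize: int = 20
    de_generations: int = 80
    f: float = 0.5
    cr: float = 0.7
    simplex_tol: float = 1e-12
    sigma: float | None = None
    seed: int | None = None
    log_scale: bool = True


def default_bounds(parameters: Sequence[str]) -> dict[str, tuple[float, float]]:
    """Default fitting bounds for kcat/Km-style parameter names."""
    out = {}
    for name in parameters:
        if name.startswith("kcat"):
            out[name] = (1e2, 1e7)
        else:
            out[name] = (1e-3, 1e2)
    return out


def _model_for_experiment(model: KineticModel, exp: Experiment) -> KineticModel:
    return model.with_constants(exp.constants) if exp.constants else model


def predict(model: KineticModel, exp: Experiment, rtol=1e-8, atol=1e-12) -> np.ndarray:
    """Model prediction at the experimental time points.

    Integrates from t = 0 (where the initial conditions are defined) and
    evaluates the dense LSODA solution at the experimental times; returns an
    array of shape (len(observed), len(times)).
    """
    m = _model_for_experiment(model, exp)
    times = exp.times
    prepend = times[0] > 0
    grid_times = np.concatenate([[0.0], times]) if prepend else times
    # reuse simulate() via an ad-hoc non-equidistant integration
    from .models import build_jacobian, build_rhs  # local to avoid cycle noise

    rhs, jac = build_rhs(m), build_jacobian(m)
    x0 = np.array([float(exp.initial_conditions[s]) for s in m.species])
    from scipy.integrate import ODEintWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ODEintWarning)
        out, info = odeint(
            rhs, x0, grid_times, Dfun=jac, rtol=rtol, atol=atol,
            full_output=True, printmessg=False, mxstep=50000,
        )
    if info["message"] != "Integration successful.":
        raise SimulationError(f"LSODA failed: {info['message']}")
    if prepend:
        out = out[1:]
    rows = [m.index(s) for s in exp.observed]
    return out.T[rows]


def ssq_objective(
    P: Mapping[str, float], model: KineticModel, data: Dataset
) -> float:
    """Non-weighted least-squares objective (mM^2) of parameters P.

    Simulation failures return :data:`PENALTY_SSQ` rather than raising, so
    stochastic optimizers can step over infeasible parameter vectors.
    """
    m = model.with_parameters(dict(P)) if P else model
    total = 0.0
    for exp in data:
        try:
            pred = predict(m, exp)
        except (SimulationError, KeyError):
            return PENALTY_SSQ
        if not np.all(np.isfinite(pred)):
            return PENALTY_SSQ
        total += float(np.sum((exp.values - pred) ** 2))
    return total


def fit_collective(
    model: KineticModel,
    data: Dataset,
    settings: EstimationSettings,
) -> ParameterEstimate:
    """Fit the free parameters of ``model`` to ``data``.

    DE/rand/1/bin explores the (log-scaled) bounded box from a uniformly
    sampled initial population; the best member is refined with Nelder-Mead.
    """
    if len(data) == 0:
        raise ValueError("dataset is empty")
    names = list(settings.bounds)
    lo = np.array([settings.bounds[n][0] for n in names], dtype=float)
    hi = np.array([settings.bounds[n][1] for n in names], dtype=float)
    if settings.log_scale:
        if np.any(lo <= 0):
            raise ValueError("log-scale fitting needs strictly positive bounds")
        tlo, thi = np.log10(lo), np.log10(hi)
        back = lambda z: 10.0**z
    else:
        tlo, thi = lo, hi
        back = lambda z: z

    def fun(z):
        return ssq_objective(dict(zip(names, back(z))), model, data)

    rng = np.random.default_rng(settings.seed)
    init = rng.uniform(tlo, thi, size=(max(settings.de_popsize, 5), len(names)))
    result = differential_evolution(
        fun,
        bounds=list(zip(tlo, thi)),
        strategy="rand1bin",
        mutation=settings.f,
        recombination=settings.cr,
        maxiter=settings.de_generations,
        init=init,
        polish=False,
        tol=0,
        seed=settings.seed,
    )
    if result.fun >= PENALTY_SSQ:
        raise EstimationFailureError(
            "every DE population member failed to simulate"
        )
    refined = minimize(
        fun,
        result.x,
        method="Nelder-Mead",
        options={
            "xatol": settings.simplex_tol,
            "fatol": settings.simplex_tol,
            "maxiter": 4000,
        },
    )
    # the simplex refinement must never lose ground on the DE optimum
    if refined.fun <= result.fun:
        best_z, best_f = refined.x, float(refined.fun)
    else:
        best_z, best_f = result.x, float(result.fun)
    values = dict(zip(names, map(float, back(best_z))))

    n_points = sum(exp.values.size for exp in data)
    sigma = settings.sigma
    if sigma is None:
        sigma = float(np.sqrt(max(best_f, 0.0) / n_points)) if n_points else 0.0
    fim = None
    ses: dict[str, float] | None = None
    if sigma > 0:
        try:
            fim = fisher_information(model.with_parameters(values), names, data, sigma)
            se_vec = standard_errors(fim)
            if se_vec is not None:
                ses = dict(zip(names, map(float, se_vec)))
        except SimulationError:
            fim = None
    return ParameterEstimate(
        values=values,
        standard_errors=ses,
        fim=fim,
        objective_value=best_f,
        sigma=sigma,
    )


# ---------------------------------------------------------------------------
# Sensitivity equations and Fisher information
# ---------------------------------------------------------------------------


def _symbolic_rate(law, subs_syms, par_syms, enz):
    if law.form == MASS_ACTION_REVERSIBLE:
        kf, kr = par_syms
        a, b = subs_syms[:2]
        q = subs_syms[2]
        return kf * a * b - kr * q
    if law.form == MM_IRREV_1S:
        kcat, km = par_syms
        (s,) = subs_syms
        return kcat * enz * s / (km + s)
    kcat, kma, kmb = par_syms
    a, b = subs_syms
    return kcat * enz * a * b / (kma * kmb + kmb * a + kma * b + a * b)


def sensitivity_system(model: KineticModel, free_params: Sequence[str]):
    """Build the sensitivity-augmented ODE right-hand side.

    The state is y = [x, vec(S)] with S = dx/dp of shape (n, q), obeying
    dS/dt = (df/dx) S + df/dp with S(0) = 0 (initial conditions are not
    fitted).  Jacobians are derived symbolically and lambdified.

    Returns ``(rhs, n, q)`` where ``rhs(y, t)`` is suitable for odeint.
    """
    import sympy as sp

    unknown = set(free_params) - set(model.parameters)
    if unknown:
        raise ValueError(f"free parameters {sorted(unknown)} not in model")
    xs = sp.symbols([f"x_{s}" for s in model.species], positive=True)
    xmap = dict(zip(model.species, xs))
    pmap = {
        name: (sp.Symbol(f"p_{name}") if name in free_params else sp.Float(val))
        for name, val in model.parameters.items()
    }
    f = [sp.S.Zero] * len(model.species)
    sidx = {s: i for i, s in enumerate(model.species)}
    for rxn in model.reactions:
        law = rxn.rate_law
        subs_syms = [xmap[s] for s in (*law.substrates, *law.products)]
        par_syms = [pmap[p] for p in law.parameters]
        enz = sp.Float(model.constants[rxn.enzyme]) if rxn.enzyme else sp.S.One
        v = _symbolic_rate(law, subs_syms, par_syms, enz)
        for s, c in rxn.stoichiometry.items():
            if c:
                f[sidx[s]] = f[sidx[s]] + c * v
    psyms = [sp.Symbol(f"p_{name}") for name in free_params]
    fvec = sp.Matrix(f)
    jx = fvec.jacobian(sp.Matrix(xs))
    jp = fvec.jacobian(sp.Matrix(psyms))
    args = (*xs, *psyms)
    f_fn = sp.lambdify(args, fvec, "numpy")
    jx_fn = sp.lambdify(args, jx, "numpy")
    jp_fn = sp.lambdify(args, jp, "numpy")
    n, q = len(model.species), len(free_params)
    pvals = np.array([float(model.parameters[p]) for p in free_params])

    def rhs(y, t):
        x = y[:n]
        S = y[n:].reshape(n, q)
        a = (*x, *pvals)
        dx = np.asarray(f_fn(*a), dtype=float).ravel()
        A = np.asarray(jx_fn(*a), dtype=float)
        B = np.asarray(jp_fn(*a), dtype=float)
        dS = A @ S + B
        return np.concatenate([dx, dS.ravel()])

    return rhs, n, q


def integrate_sensitivities(
    model: KineticModel,
    free_params: Sequence[str],
    ic: Mapping[str, float],
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
):
    """Integrate states and sensitivities; returns (states, S).

    ``states`` has shape (len(times), n); ``S`` has shape
    (len(times), n, q) with S(0) = 0.
    """
    rhs, n, q = sensitivity_system(model, free_params)
    times = np.asarray(times, dtype=float)
    prepend = times[0] > 0
    tgrid = np.concatenate([[0.0], times]) if prepend else times
    y0 = np.zeros(n * (1 + q))
    y0[:n] = [float(ic[s]) for s in model.species]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out, info = odeint(
            rhs, y0, tgrid, rtol=rtol, atol=atol, full_output=True,
            printmessg=False, mxstep=20000,
        )
    if info["message"] != "Integration successful.":
        raise SimulationError(f"sensitivity integration failed: {info['message']}")
    if prepend:
        out = out[1:]
    states = out[:, :n]
    S = out[:, n:].reshape(len(times), n, q)
    return states, S


def fisher_information(
    model: KineticModel,
    free_params: Sequence[str],
    data: Dataset,
    sigma: float | Mapping[str, float],
) -> np.ndarray:
    """Fisher information matrix F = sum S^T V^-1 S over all measured points.

    ``sigma`` is the measurement error SD (mM), either a scalar or a map
    per observed species; V is taken diagonal.
    """
    q = len(free_params)
    fim = np.zeros((q, q))
    for exp in data:
        m = _model_for_experiment(model, exp)
        _, S = integrate_sensitivities(m, free_params, exp.initial_conditions, exp.times)
        for s_name in exp.observed:
            if isinstance(sigma, Mapping):
                sd = float(sigma[s_name])
            else:
                sd = float(sigma)
            if sd <= 0:
                raise ValueError("measurement error SD must be positive")
            rows = S[:, m.index(s_name), :]  # (n_times, q)
            fim += rows.T @ rows / sd**2
    return fim


def standard_errors(fim: np.ndarray) -> np.ndarray | None:
    """Cramér-Rao lower-bound standard errors from the FIM.

    Returns sqrt(diag(inv(F))), or None (with a :class:`SloppinessWarning`)
    when F is singular or has condition number above 1e12.
    """
    fim = np.asarray(fim, dtype=float)
    cond = np.linalg.cond(fim)
    if not np.isfinite(cond) or cond > SLOPPINESS_CONDITION:
        warnings.warn(
            f"Fisher information matrix is ill-conditioned (cond={cond:.2e}); "
            "standard errors withheld — parameters are sloppy",
            SloppinessWarning,
            stacklevel=2,
        )
        return None
    return np.sqrt(np.diag(np.linalg.inv(fim)))
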