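"""Kinetic ODE models of the glyoxalase pathway and their simulation.

Units are fixed throughout the package: concentrations in mM, time in min,
``kcat`` in min^-1, ``Km`` in mM, the non-enzymatic rate constants ``kf`` in
mM^-1 min^-1 and ``kr`` in min^-1.

Two candidate models of the glyoxalase system are shipped.  In both,
glutathione (GSH) and methylglyoxal (MGO) condense non-enzymatically and
reversibly into a hemithioacetal (HTA), and glyoxalase II hydrolyses
S-D-lactoylglutathione (SDLGS) back to GSH (plus D-lactate, a pure sink that
is not tracked).  The models differ in the kinetics of glyoxalase I:

* model 1 — glyoxalase I isomerizes HTA with irreversible one-substrate
  Michaelis-Menten kinetics;
* model 2 — glyoxalase I binds GSH and MGO directly as sequential substrates,
  with a simplified irreversible two-substrate Michaelis-Menten rate law whose
  constant denominator term is the product of the two Michaelis constants.

The two-substrate rate law (and the model ODEs) are reconstructed from the
textual description of the mechanism — the standard sequential steady-state
form with constant term Km_GSH*Km_MGO:

    v = kcat*E*[GSH]*[MGO] / (Km_GSH*Km_MGO + Km_MGO*[GSH]
                              + Km_GSH*[MGO] + [GSH]*[MGO])

Enzymes are treated as constant-concentration parameters (aggregate rate
laws, no enzyme-intermediate species).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.integrate import odeint, ODEintWarning

from .errors import ModelDefinitionError, SimulationError, UnsupportedRateLawError

__all__ = [
    "MASS_ACTION_REVERSIBLE",
    "MM_IRREV_1S",
    "MM_IRREV_2S",
    "RateLaw",
    "Reaction",
    "KineticModel",
    "TimeGrid",
    "TimeCourse",
    "rate",
    "build_rhs",
    "build_jacobian",
    "simulate",
    "reaction_rates",
    "build_glyoxalase_model",
    "GLYOXALASE_SPECIES",
    "TABLE1_PARAMETERS",
    "TABLE1_STANDARD_ERRORS",
    "DEFAULT_ENZYMES",
]

# Supported rate-law forms
MASS_ACTION_REVERSIBLE = "mass_action_reversible"
MM_IRREV_1S = "michaelis_menten_irrev_1substrate"
MM_IRREV_2S = "michaelis_menten_irrev_2substrate_simplified"

#: (number of substrates, number of products, number of parameters) per form
_FORM_ARITY = {
    MASS_ACTION_REVERSIBLE: (2, 1, 2),  # kf, kr
    MM_IRREV_1S: (1, 0, 2),             # kcat, Km
    MM_IRREV_2S: (2, 0, 3),             # kcat, KmA, KmB
}


@dataclass(frozen=True)
class RateLaw:
    """A rate-law form bound to species and parameter names.

    ``substrates`` and ``products`` are species identifiers; ``parameters``
    are parameter names resolved against the owning model's parameter map.
    For :data:`MASS_ACTION_REVERSIBLE` the product (hemithioacetal) enters
    the reverse term; the Michaelis-Menten forms are irreversible and have
    no kinetically active product.
    """

    form: str
    substrates: tuple[str, ...]
    parameters: tuple[str, ...]
    products: tuple[str, ...] = ()

    def __post_init__(self):
        if self.form not in _FORM_ARITY:
            raise UnsupportedRateLawError(f"unknown rate-law form {self.form!r}")
        ns, npr, npar = _FORM_ARITY[self.form]
        if len(self.substrates) != ns:
            raise ModelDefinitionError(
                f"{self.form} expects {ns} substrates, got {self.substrates}"
            )
        if len(self.products) != npr:
            raise ModelDefinitionError(
                f"{self.form} expects {npr} kinetically active products"
            )
        if len(self.parameters) != npar:
            raise ModelDefinitionError(
                f"{self.form} expects {npar} parameters, got {self.parameters}"
            )


@dataclass(frozen=True)
class Reaction:
    """A stoichiometry map plus a rate law; ``enzyme`` names a constant-
    concentration species of the model (None for non-enzymatic steps)."""

    name: str
    stoichiometry: Mapping[str, int]
    rate_law: RateLaw
    enzyme: str | None = None


@dataclass(frozen=True)
class KineticModel:
    """An ODE kinetic model: dynamic species, constant enzyme concentrations,
    kinetic parameters and reactions."""

    name: str
    species: tuple[str, ...]
    constants: Mapping[str, float]
    parameters: Mapping[str, float]
    reactions: tuple[Reaction, ...]

    def __post_init__(self):
        if len(set(self.species)) != len(self.species):
            raise ModelDefinitionError("species names must be unique")
        declared = set(self.species)
        for rxn in self.reactions:
            law = rxn.rate_law
            for p in law.parameters:
                if p not in self.parameters:
                    raise ModelDefinitionError(
                        f"reaction {rxn.name!r}: parameter {p!r} not in model"
                    )
            for s in (*law.substrates, *law.products):
                if s not in declared:
                    raise ModelDefinitionError(
                        f"reaction {rxn.name!r}: species {s!r} not declared"
                    )
            for s in rxn.stoichiometry:
                if s not in declared:
                    raise ModelDefinitionError(
                        f"reaction {rxn.name!r}: stoichiometry references "
                        f"undeclared species {s!r}"
                    )
            if rxn.enzyme is not None and rxn.enzyme not in self.constants:
                raise ModelDefinitionError(
                    f"reaction {rxn.name!r}: enzyme {rxn.enzyme!r} not a "
                    f"declared constant"
                )

    def index(self, species: str) -> int:
        return self.species.index(species)

    def with_parameters(self, updates: Mapping[str, float]) -> "KineticModel":
        """Return a copy with some parameter values replaced."""
        unknown = set(updates) - set(self.parameters)
        if unknown:
            raise ModelDefinitionError(f"unknown parameters {sorted(unknown)}")
        params = dict(self.parameters)
        params.update(updates)
        return replace(self, parameters=params)

    def with_constants(self, updates: Mapping[str, float]) -> "KineticModel":
        """Return a copy with some constant (enzyme) concentrations replaced."""
        unknown = set(updates) - set(self.constants)
        if unknown:
            raise ModelDefinitionError(f"unknown constants {sorted(unknown)}")
        consts = dict(self.constants)
        consts.update(updates)
        return replace(self, constants=consts)


@dataclass(frozen=True)
class TimeGrid:
    """Equidistant time grid: ``m`` points t0, t0+dt, ..., t0+(m-1)*dt (min)."""

    t0: float
    dt: float
    m: int

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.m < 2:
            raise ValueError("a grid needs at least two points")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.m)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.m - 1)

    def refined(self, factor: int = 2) -> "TimeGrid":
        """Grid with ``dt`` divided by ``factor`` over the same span."""
        return TimeGrid(self.t0, self.dt / factor, (self.m - 1) * factor + 1)


@dataclass(frozen=True)
class TimeCourse:
    """Concentration trajectories (mM) of all model species on a grid.

    ``values`` has shape (n_species, m), rows in ``species`` order.
    """

    grid: TimeGrid
    species: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.species), self.grid.m):
            raise ValueError(
                f"values shape {v.shape} inconsistent with "
                f"{len(self.species)} species x {self.grid.m} points"
            )
        object.__setattr__(self, "values", v)

    def get(self, species: str) -> np.ndarray:
        return self.values[self.species.index(species)]


def rate(
    rate_law: RateLaw,
    state: Mapping[str, float],
    params: Mapping[str, float],
    enzyme_conc: float = 0.0,
) -> float:
    """Evaluate a rate law (mM min^-1) at a concentration state.

    ``enzyme_conc`` is ignored by the mass-action form.
    """
    try:
        s = [state[name] for name in rate_law.substrates]
        p = [params[name] for name in rate_law.parameters]
    except KeyError as exc:
        raise ModelDefinitionError(f"missing species or parameter: {exc}") from exc
    if rate_law.form == MASS_ACTION_REVERSIBLE:
        kf, kr = p
        try:
            q = state[rate_law.products[0]]
        except KeyError as exc:
            raise ModelDefinitionError(f"missing species: {exc}") from exc
        return kf * s[0] * s[1] - kr * q
    if rate_law.form == MM_IRREV_1S:
        kcat, km = p
        return kcat * enzyme_conc * s[0] / (km + s[0])
    if rate_law.form == MM_IRREV_2S:
        kcat, kma, kmb = p
        a, b = s
        denom = kma * kmb + kmb * a + kma * b + a * b
        return kcat * enzyme_conc * a * b / denom
    raise UnsupportedRateLawError(f"unknown rate-law form {rate_law.form!r}")


def _compile_reactions(model: KineticModel):
    """Compile per-reaction rate closures and stoichiometry index lists."""
    sidx = {s: i for i, s in enumerate(model.species)}
    compiled = []
    for rxn in model.reactions:
        law = rxn.rate_law
        p = [float(model.parameters[name]) for name in law.parameters]
        enz = float(model.constants[rxn.enzyme]) if rxn.enzyme else 0.0
        stoich = [(sidx[s], float(c)) for s, c in rxn.stoichiometry.items() if c]
        if law.form == MASS_ACTION_REVERSIBLE:
            a, b = (sidx[s] for s in law.substrates)
            q = sidx[law.products[0]]
            kf, kr = p

            def v(x, a=a, b=b, q=q, kf=kf, kr=kr):
                return kf * x[a] * x[b] - kr * x[q]

            def grad(x, a=a, b=b, q=q, kf=kf, kr=kr):
                return [(a, kf * x[b]), (b, kf * x[a]), (q, -kr)]

        elif law.form == MM_IRREV_1S:
            (si,) = (sidx[s] for s in law.substrates)
            vmax = p[0] * enz
            km = p[1]

            def v(x, si=si, vmax=vmax, km=km):
                return vmax * x[si] / (km + x[si])

            def grad(x, si=si, vmax=vmax, km=km):
                return [(si, vmax * km / (km + x[si]) ** 2)]

        else:  # MM_IRREV_2S
            a, b = (sidx[s] for s in law.substrates)
            vmax = p[0] * enz
            kma, kmb = p[1], p[2]

            def v(x, a=a, b=b, vmax=vmax, kma=kma, kmb=kmb):
                denom = kma * kmb + kmb * x[a] + kma * x[b] + x[a] * x[b]
                return vmax * x[a] * x[b] / denom

            def grad(x, a=a, b=b, vmax=vmax, kma=kma, kmb=kmb):
                denom = kma * kmb + kmb * x[a] + kma * x[b] + x[a] * x[b]
                da = vmax * kma * x[b] * (kmb + x[b]) / denom**2
                db = vmax * kmb * x[a] * (kma + x[a]) / denom**2
                return [(a, da), (b, db)]

        compiled.append((v, grad, stoich))
    return compiled


def build_rhs(model: KineticModel):
    """Return the ODE right-hand side f(x, t) -> dx/dt for a model."""
    compiled = _compile_reactions(model)
    n = len(model.species)

    def rhs(x, t):
        dx = np.zeros(n)
        for v, _grad, stoich in compiled:
            r = v(x)
            for i, c in stoich:
                dx[i] += c * r
        return dx

    return rhs


def build_jacobian(model: KineticModel):
    """Return the analytic Jacobian J(x, t) = d f / d x (n x n)."""
    compiled = _compile_reactions(model)
    n = len(model.species)

    def jac(x, t):
        J = np.zeros((n, n))
        for _v, grad, stoich in compiled:
            for j, dv in grad(x):
                for i, c in stoich:
                    J[i, j] += c * dv
        return J

    return jac


def simulate(
    model: KineticModel,
    ic: Mapping[str, float],
    grid: TimeGrid,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> TimeCourse:
    """Integrate the model ODEs on an equidistant grid with LSODA.

    ``ic`` must assign a non-negative concentration (mM) to every dynamic
    species.  LSODA switches automatically between non-stiff and stiff
    methods; the glyoxalase models are stiff (kcat up to 1e5 min^-1 against
    mM concentrations), hence the tight default tolerances and the analytic
    Jacobian passed to the integrator.
    """
    missing = set(model.species) - set(ic)
    if missing:
        raise ModelDefinitionError(f"initial conditions missing {sorted(missing)}")
    x0 = np.array([float(ic[s]) for s in model.species])
    if np.any(x0 < 0):
        raise ModelDefinitionError("initial concentrations must be non-negative")
    rhs = build_rhs(model)
    jac = build_jacobian(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ODEintWarning)
        out, info = odeint(
            rhs,
            x0,
            grid.times,
            Dfun=jac,
            rtol=rtol,
            atol=atol,
            full_output=True,
            printmessg=False,
        )
    if info["message"] != "Integration successful.":
        reached = float(info["tcur"][-1]) if len(info.get("tcur", [])) else grid.t0
        raise SimulationError(
            f"LSODA failed for model {model.name!r}: {info['message']}",
            time_reached=reached,
        )
    return TimeCourse(grid=grid, species=model.species, values=out.T)


def reaction_rates(model: KineticModel, tc: TimeCourse) -> dict[str, np.ndarray]:
    """Evaluate every reaction rate (mM min^-1) along a simulated trajectory."""
    compiled = _compile_reactions(model)
    out: dict[str, np.ndarray] = {}
    for rxn, (v, _g, _s) in zip(model.reactions, compiled):
        out[rxn.name] = np.array([v(tc.values[:, j]) for j in range(tc.grid.m)])
    return out


# ---------------------------------------------------------------------------
# Shipped glyoxalase models
# ---------------------------------------------------------------------------

GLYOXALASE_SPECIES = ("GSH", "MGO", "HTA", "SDLGS")

#: Default kinetic parameters per model variant (collective-fit estimates for
#: S. cerevisiae glyoxalase I and bovine liver glyoxalase II; the
#: non-enzymatic constants are literature values).
TABLE1_PARAMETERS: dict[int, dict[str, float]] = {
    1: {
        "kcat_GLOI": 8.0e4,   # min^-1
        "Km_HTA": 0.2,        # mM
        "kcat_GLOII": 3.0e2,  # min^-1
        "Km_SDLGS": 3.0,      # mM
        "kf": 0.34,           # mM^-1 min^-1
        "kr": 1.01,           # min^-1
    },
    2: {
        "kcat_GLOI": 1.7e5,   # min^-1
        "Km_GSH": 0.87,       # mM
        "Km_MGO": 1.2,        # mM
        "kcat_GLOII": 3.0e2,  # min^-1
        "Km_SDLGS": 3.0,      # mM
        "kf": 0.34,           # mM^-1 min^-1
        "kr": 1.01,           # min^-1
    },
}

#: Reported standard errors of the fitted parameters (same units).
TABLE1_STANDARD_ERRORS: dict[int, dict[str, float]] = {
    1: {"kcat_GLOI": 3.0e4, "Km_HTA": 0.14, "kcat_GLOII": 2.2e2, "Km_SDLGS": 2.1},
    2: {
        "kcat_GLOI": 0.38e5,
        "Km_GSH": 0.11,
        "Km_MGO": 0.19,
        "kcat_GLOII": 2.2e2,
        "Km_SDLGS": 2.1,
    },
}

#: Default constant enzyme concentrations (mM) of the shipped design problem.
DEFAULT_ENZYMES = {"E_GLOI": 2.0e-3, "E_GLOII": 4.0e-4}


def build_glyoxalase_model(
    variant: int,
    params: Mapping[str, float] | None = None,
    enzymes: Mapping[str, float] | None = None,
) -> KineticModel:
    """Build glyoxalase candidate model 1 or 2.

    Model 1 (hemithioacetal is the glyoxalase I substrate)::

        d[GSH]/dt   = -v_ne + v_GII      d[MGO]/dt   = -v_ne
        d[HTA]/dt   =  v_ne - v_GI       d[SDLGS]/dt =  v_GI - v_GII

    Model 2 (GSH and MGO are sequential glyoxalase I substrates; HTA is an
    off-pathway reservoir)::

        d[GSH]/dt   = -v_ne - v_GI + v_GII    d[MGO]/dt = -v_ne - v_GI
        d[HTA]/dt   =  v_ne                   d[SDLGS]/dt = v_GI - v_GII

    ``params``/``enzymes`` override the shipped defaults
    (:data:`TABLE1_PARAMETERS`, :data:`DEFAULT_ENZYMES`).
    """
    if variant not in (1, 2):
        raise ValueError(f"variant must be 1 or 2, got {variant!r}")
    p = dict(TABLE1_PARAMETERS[variant])
    if params:
        p.update(params)
    e = dict(DEFAULT_ENZYMES)
    if enzymes:
        e.update(enzymes)

    ne = Reaction(
        name="hta_formation",
        stoichiometry={"GSH": -1, "MGO": -1, "HTA": +1},
        rate_law=RateLaw(
            MASS_ACTION_REVERSIBLE,
            substrates=("GSH", "MGO"),
            parameters=("kf", "kr"),
            products=("HTA",),
        ),
    )
    gloII = Reaction(
        name="glyoxalase_II",
        stoichiometry={"SDLGS": -1, "GSH": +1},
        rate_law=RateLaw(
            MM_IRREV_1S,
            substrates=("SDLGS",),
            parameters=("kcat_GLOII", "Km_SDLGS"),
        ),
        enzyme="E_GLOII",
    )
    if variant == 1:
        gloI = Reaction(
            name="glyoxalase_I",
            stoichiometry={"HTA": -1, "SDLGS": +1},
            rate_law=RateLaw(
                MM_IRREV_1S,
                substrates=("HTA",),
                parameters=("kcat_GLOI", "Km_HTA"),
            ),
            enzyme="E_GLOI",
        )
    else:
        gloI = Reaction(
            name="glyoxalase_I",
            stoichiometry={"GSH": -1, "MGO": -1, "SDLGS": +1},
            rate_law=RateLaw(
                MM_IRREV_2S,
                substrates=("GSH", "MGO"),
                parameters=("kcat_GLOI", "Km_GSH", "Km_MGO"),
            ),
            enzyme="E_GLOI",
        )
    return KineticModel(
        name=f"glyoxalase_model_{variant}",
        species=GLYOXALASE_SPECIES,
        constants=e,
        parameters=p,
        reactions=(ne, gloI, gloII),
    )
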