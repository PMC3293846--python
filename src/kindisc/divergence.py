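"""Divergence measures between predicted time courses.

The central measure is the Kullback-Leibler distance extended to the space
of positive functions, evaluated as an un-normalized discrete sum over the
equidistant grid points t_i and the observable species j:

    I(f, g) = sum_j sum_i [ f_j(t_i) ln(f_j(t_i)/g_j(t_i)) - f_j(t_i) + g_j(t_i) ]

I(f, g) >= 0 with equality iff f == g at all observable grid points, and it
is directed: I(f, g) != I(g, f) in general, which is why design optimization
maximizes both directions simultaneously.  Because concentrations can be
exactly zero (e.g. the reaction product at t = 0), both arguments are
clipped below at ``eps`` before taking logarithms.

Two L2 comparison norms are provided: the simple (non-weighted) squared-L2
sum and a variant weighting each observable by the inverse squared time-mean
of the first argument.
"""

from __future__ import annotations

from itertools import permutations
from typing import Sequence

import numpy as np

from .errors import DegenerateWeightingError, IncompatibleTimeCourseError
from .models import TimeCourse

__all__ = [
    "kl_extended",
    "l2_simple",
    "l2_weighted",
    "pairwise_objectives",
]

DEFAULT_EPS = 1e-12  # mM; clip level before logarithms

#: Most negative concentration tolerated before a domain error.  Stiff
#: integration at atol ~ 1e-12 legitimately produces values a few orders of
#: magnitude below zero; anything beyond this is treated as a real negative.
NEGATIVE_TOL = 1e-8  # mM


def _observable_matrix(tc: TimeCourse, observables: Sequence[str], eps: float):
    idx = [tc.species.index(s) for s in observables]
    vals = tc.values[idx]
    if np.any(vals < -max(eps, NEGATIVE_TOL)):
        raise ValueError(
            "negative concentrations below -eps in time course; not a valid "
            "argument for a positive-function divergence"
        )
    return vals


def _check_compatible(f: TimeCourse, g: TimeCourse, observables: Sequence[str]):
    if not observables:
        raise ValueError("observable set must be non-empty")
    gf, gg = f.grid, g.grid
    same = (
        gf.m == gg.m
        and np.isclose(gf.t0, gg.t0)
        and np.isclose(gf.dt, gg.dt)
    )
    if not same:
        raise IncompatibleTimeCourseError("time courses are on different grids")
    for s in observables:
        if s not in f.species or s not in g.species:
            raise IncompatibleTimeCourseError(
                f"observable {s!r} missing from a time course"
            )


def kl_extended(
    f: TimeCourse,
    g: TimeCourse,
    observables: Sequence[str],
    eps: float = DEFAULT_EPS,
) -> float:
    """Directed extended Kullback-Leibler distance I(f, g) over observables.

    Dimensionless after unit cancellation inside the logarithm (each term is
    x ln(x/y) - x + y in mM, summed without a dt factor; only relative
    comparison across designs is meaningful).
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    _check_compatible(f, g, observables)
    F = np.clip(_observable_matrix(f, observables, eps), eps, None)
    G = np.clip(_observable_matrix(g, observables, eps), eps, None)
    return float(np.sum(F * np.log(F / G) - F + G))


def l2_simple(f: TimeCourse, g: TimeCourse, observables: Sequence[str]) -> float:
    """Simple (non-weighted) squared-L2 divergence: sum_j sum_i (f-g)^2 (mM^2)."""
    _check_compatible(f, g, observables)
    F = _observable_matrix(f, observables, np.inf)
    G = _observable_matrix(g, observables, np.inf)
    return float(np.sum((F - G) ** 2))


def l2_weighted(f: TimeCourse, g: TimeCourse, observables: Sequence[str]) -> float:
    """Squared-L2 divergence weighted per observable by 1/mean_i[f_j]^2.

    The weight uses the time-mean of the *first* argument, making the
    measure asymmetric on generic inputs.
    """
    _check_compatible(f, g, observables)
    F = _observable_matrix(f, observables, np.inf)
    G = _observable_matrix(g, observables, np.inf)
    means = F.mean(axis=1)
    if np.any(means <= 0):
        raise DegenerateWeightingError(
            "zero time-mean for an observable; weighted L2 undefined"
        )
    return float(np.sum(((F - G) ** 2).sum(axis=1) / means**2))


def pairwise_objectives(
    time_courses: Sequence[TimeCourse],
    observables: Sequence[str],
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """All k(k-1) directed extended-KL distances between k model predictions.

    Order: lexicographic over ordered index pairs, i.e. for k models the
    entries are I(f_a, f_b) for (a, b) in
    ``itertools.permutations(range(k), 2)`` — for k = 2 this is
    [I(f1, f2), I(f2, f1)]; for k = 3 a 6-vector.
    """
    if len(time_courses) < 2:
        raise ValueError("need at least two model predictions")
    return np.array(
        [
            kl_extended(time_courses[a], time_courses[b], observables, eps)
            for a, b in permutations(range(len(time_courses)), 2)
        ]
    )
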