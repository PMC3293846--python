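"""Generalized Differential Evolution 3 (GDE3) for multi-objective maximization.

GDE3 extends DE/rand/1/bin with Pareto-dominance selection: a trial vector
replaces its target when it dominates it, is discarded when dominated, and
is kept *alongside* the target when the two are mutually non-dominated.  The
grown population is then restored to size NP by non-dominated sorting
followed by removal of the most crowded members of the last retained front
(k-nearest-neighbor crowding).

Maximization is the native sense throughout this module: ``u`` dominates
``v`` iff every objective of ``u`` is >= the corresponding objective of
``v`` with at least one strict inequality.  Negate objectives to minimize.

Non-dominated sorting is done with a divide-and-conquer dominance tree: the
population is recursively split in halves, each half sorted into a tree of
mutually non-dominated sibling roots with dominated solutions stored as
subtrees, and the halves merged by pairwise dominance comparison of roots.
A naive O(n^2) repeated-extraction sort is provided as an independent
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InfeasibleBoundsError

__all__ = [
    "Solution",
    "Population",
    "GDE3Settings",
    "GDE3Result",
    "dominates",
    "sort_nondominated_naive",
    "sort_nondominated_tree",
    "reduce_crowded",
    "gde3_generation",
    "gde3_run",
]


@dataclass(eq=False)  # identity semantics: ndarray fields are not comparable
class Solution:
    """A decision vector with its (maximized) objective vector."""

    decision: np.ndarray
    objectives: np.ndarray | None = None
    feasible: bool = True

    def __post_init__(self):
        self.decision = np.asarray(self.decision, dtype=float)
        if self.objectives is not None:
            self.objectives = np.asarray(self.objectives, dtype=float)


@dataclass
class Population:
    solutions: list[Solution]
    bounds: np.ndarray  # shape (d, 2): lower, upper per decision dimension
    generation: int = 0

    def decisions(self) -> np.ndarray:
        return np.array([s.decision for s in self.solutions])


@dataclass(frozen=True)
class GDE3Settings:
    """Optimizer settings.

    Defaults follow the shipped study conditions: F = 0.5, CR = 0.7,
    at most 200 generations, and termination when fewer than 5% of the
    population improves for 20 consecutive generations.  NP defaults to 40.
    """

    np_size: int = 40
    f: float = 0.5
    cr: float = 0.7
    max_generations: int = 200
    stall_window: int = 20
    stall_fraction: float = 0.05
    k_crowding: int = 3
    seed: int | None = None
    bound_retries: int = 100

    def __post_init__(self):
        if not (0 < self.cr <= 1):
            raise ValueError("CR must be in (0, 1]")
        if self.f <= 0:
            raise ValueError("F must be positive")
        if self.np_size < 4:
            raise ValueError("NP must be at least 4 (DE/rand/1 needs 3 donors)")


@dataclass
class GDE3Result:
    """Final front partition plus per-generation improvement history."""

    fronts: list[list[Solution]]
    population: Population
    history: list[float] = field(default_factory=list)
    seed: int | None = None
    generations: int = 0

    @property
    def front(self) -> list[Solution]:
        return self.fronts[0]


def dominates(u: Solution, v: Solution) -> bool:
    """True iff u Pareto-dominates v in the maximization sense."""
    a, b = u.objectives, v.objectives
    if a is None or b is None:
        raise ValueError("both solutions must be evaluated")
    if len(a) != len(b):
        raise ValueError("objective vectors have different lengths")
    return bool(np.all(a >= b) and np.any(a > b))


# ---------------------------------------------------------------------------
# Non-dominated sorting
# ---------------------------------------------------------------------------


def _require_evaluated(solutions):
    for s in solutions:
        if s.objectives is None:
            raise ValueError("population contains unevaluated solutions")


def sort_nondominated_naive(solutions: list[Solution]) -> list[list[Solution]]:
    """O(n^2)-per-front sort by repeated extraction of the non-dominated set."""
    _require_evaluated(solutions)
    remaining = list(solutions)
    fronts: list[list[Solution]] = []
    while remaining:
        front = [
            s
            for s in remaining
            if not any(dominates(o, s) for o in remaining if o is not s)
        ]
        fronts.append(front)
        kept = set(map(id, front))
        remaining = [s for s in remaining if id(s) not in kept]
    return fronts


class _Node:
    __slots__ = ("sol", "children")

    def __init__(self, sol: Solution):
        self.sol = sol
        self.children: list[_Node] = []


def _merge(left: list[_Node], right: list[_Node]) -> list[_Node]:
    """Conquer step: merge two sibling lists (each mutually non-dominated).

    Dominated roots are pushed down into the dominating root's child tree
    (itself kept as a valid sibling list by recursive merging); surviving
    roots of both sides form the merged sibling list.
    """
    out: list[_Node] = []
    for l in left:
        dominated_by: _Node | None = None
        rest: list[_Node] = []
        for r in right:
            if dominated_by is not None:
                rest.append(r)
            elif dominates(l.sol, r.sol):
                l.children = _merge(l.children, [r])
            elif dominates(r.sol, l.sol):
                dominated_by = r
                rest.append(r)
            else:
                rest.append(r)
        right = rest
        if dominated_by is not None:
            dominated_by.children = _merge(dominated_by.children, [l])
        else:
            out.append(l)
    out.extend(right)
    return out


def _build_tree(nodes: list[_Node]) -> list[_Node]:
    """Divide step: recursively halve, then conquer by merging."""
    if len(nodes) <= 1:
        return nodes
    mid = len(nodes) // 2
    return _merge(_build_tree(nodes[:mid]), _build_tree(nodes[mid:]))


def sort_nondominated_tree(solutions: list[Solution]) -> list[list[Solution]]:
    """Divide-and-conquer dominance-tree non-dominated sort.

    Returns the same front partition (as sets) as
    :func:`sort_nondominated_naive`.
    """
    _require_evaluated(solutions)
    roots = _build_tree([_Node(s) for s in solutions])
    fronts: list[list[Solution]] = []
    while roots:
        fronts.append([n.sol for n in roots])
        nxt: list[_Node] = []
        for n in roots:
            if n.children:
                nxt = _merge(nxt, n.children)
        roots = nxt
    return fronts


# ---------------------------------------------------------------------------
# Crowding reduction
# ---------------------------------------------------------------------------


def reduce_crowded(
    front: list[Solution], target_size: int, k: int = 3
) -> list[Solution]:
    """Prune a front to ``target_size`` by iteratively removing the most
    crowded solution.

    Crowding is measured in raw objective space as the Euclidean distance to
    the k-th nearest neighbor; after each removal the distances are
    recomputed.  Ties break toward the lowest index, making the reduction
    deterministic.
    """
    if target_size > len(front):
        raise ValueError("target_size exceeds front size")
    if k >= len(front):
        raise ValueError("k must be smaller than the front size")
    if k < 1:
        raise ValueError("k must be at least 1")
    sols = list(front)
    while len(sols) > target_size:
        obj = np.array([s.objectives for s in sols])
        dist = squareform(pdist(obj))
        np.fill_diagonal(dist, np.inf)
        k_eff = min(k, len(sols) - 1)  # the shrinking front can drop below k+1
        kth = np.sort(dist, axis=1)[:, k_eff - 1]
        sols.pop(int(np.argmin(kth)))  # argmin takes the lowest index on ties
    return sols


# ---------------------------------------------------------------------------
# GDE3 proper
# ---------------------------------------------------------------------------


def _trial_vector(X, i, lower, upper, f, cr, rng, retries):
    """DE/rand/1/bin trial for target i; resampled until inside bounds."""
    n, d = X.shape
    for _ in range(retries):
        choices = [j for j in range(n) if j != i]
        r1, r2, r3 = rng.choice(choices, size=3, replace=False)
        mutant = X[r1] + f * (X[r2] - X[r3])
        cross = rng.random(d) < cr
        cross[rng.integers(d)] = True  # guarantee at least one crossed coord
        trial = np.where(cross, mutant, X[i])
        if np.all(trial >= lower) and np.all(trial <= upper):
            return trial
    raise InfeasibleBoundsError(
        f"could not generate an in-bounds trial vector in {retries} attempts"
    )


def gde3_generation(
    pop: Population,
    objective_fn,
    settings: GDE3Settings,
    rng: np.random.Generator,
) -> tuple[Population, int]:
    """One GDE3 generation; returns the new population and the improvement
    count (target replacements + non-dominated insertions)."""
    _require_evaluated(pop.solutions)
    lower, upper = pop.bounds[:, 0], pop.bounds[:, 1]
    X = pop.decisions()
    np_size = len(pop.solutions)
    new: list[Solution] = []
    improvements = 0
    for i, target in enumerate(pop.solutions):
        trial_x = _trial_vector(
            X, i, lower, upper, settings.f, settings.cr, rng, settings.bound_retries
        )
        trial = Solution(trial_x, np.asarray(objective_fn(trial_x), dtype=float))
        if dominates(trial, target):
            new.append(trial)
            improvements += 1
        elif dominates(target, trial):
            new.append(target)
        else:
            new.append(target)
            new.append(trial)
            improvements += 1
    if len(new) > np_size:
        fronts = sort_nondominated_tree(new)
        kept: list[Solution] = []
        for fr in fronts:
            if len(kept) + len(fr) <= np_size:
                kept.extend(fr)
            else:
                room = np_size - len(kept)
                if room > 0:
                    k = min(settings.k_crowding, len(fr) - 1)
                    kept.extend(reduce_crowded(fr, room, k))
                break
        new = kept
    return Population(new, pop.bounds, pop.generation + 1), improvements


def gde3_run(
    objective_fn,
    bounds: np.ndarray,
    settings: GDE3Settings,
) -> GDE3Result:
    """Run GDE3 on a box-bounded maximization problem.

    ``objective_fn(x)`` maps a decision vector to an objective vector (all
    maximized).  The initial population is sampled uniformly inside
    ``bounds``; the run stops when the improvement fraction stays at or
    below ``stall_fraction`` for ``stall_window`` consecutive generations,
    or after ``max_generations``.  Reproducible for a fixed seed.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2:
        raise ValueError("bounds must have shape (d, 2)")
    if np.any(bounds[:, 0] > bounds[:, 1]):
        raise ValueError("lower bounds exceed upper bounds")
    rng = np.random.default_rng(settings.seed)
    X0 = rng.uniform(bounds[:, 0], bounds[:, 1], size=(settings.np_size, bounds.shape[0]))
    pop = Population(
        [Solution(x, np.asarray(objective_fn(x), dtype=float)) for x in X0],
        bounds,
    )
    history: list[float] = []
    stall = 0
    gen = 0
    for gen in range(1, settings.max_generations + 1):
        pop, improvements = gde3_generation(pop, objective_fn, settings, rng)
        frac = improvements / settings.np_size
        history.append(frac)
        stall = stall + 1 if frac <= settings.stall_fraction else 0
        if stall >= settings.stall_window:
            break
    fronts = sort_nondominated_tree(pop.solutions)
    return GDE3Result(
        fronts=fronts,
        population=pop,
        history=history,
        seed=settings.seed,
        generations=pop.generation,
    )
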