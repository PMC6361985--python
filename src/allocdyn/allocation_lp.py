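"""Linear allocation optimization over a box-on-simplex polytope.

The benchmark optimization task gives a linear performance objective
``c . x`` over the decision space {l <= x <= u, sum x = s}.  Because the
feasible set is a bounded polytope, an optimum is attained at a vertex, so
the solver scores every vertex from exact enumeration — no iterative LP
machinery, no tolerance drift, and all alternative optima fall out for free.
A grading helper classifies a proposed allocation (e.g. a subject's answer)
as feasible/optimal with its objective gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import DecisionPolytope, VertexSet, contains, enumerate_vertices, is_empty

__all__ = ["AllocationLP", "LPSolution", "GradeReport", "grade_solution", "solve"]

#: Relative tie tolerance for listing alternative optima (degenerate
#: objectives, e.g. equal coefficients, make every vertex optimal).
TIE_RTOL = 1e-9


@dataclass(frozen=True)
class AllocationLP:
    """maximize c . x  over a :class:`~allocdyn.geometry.DecisionPolytope`."""

    c: np.ndarray
    polytope: DecisionPolytope

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float)
        if c.shape != (self.polytope.m,):
            raise ValueError(
                f"objective has {c.size} coefficients for {self.polytope.m} dimensions")
        object.__setattr__(self, "c", c)


@dataclass(frozen=True)
class LPSolution:
    x_star: np.ndarray
    objective: float
    all_optima: VertexSet


@dataclass(frozen=True)
class GradeReport:
    feasible: bool
    optimal: bool
    gap: float


def solve(problem: AllocationLP) -> LPSolution:
    """Maximize over the polytope by scoring all enumerated vertices.

    ``all_optima`` lists every vertex whose objective is within a relative
    tie tolerance of the best.
    """
    if is_empty(problem.polytope):
        raise ValueError("infeasible problem: the decision polytope is empty")
    vertices = enumerate_vertices(problem.polytope)
    scores = vertices.vertices @ problem.c
    best = float(scores.max())
    tie = TIE_RTOL * max(1.0, abs(best))
    optima = vertices.vertices[scores >= best - tie]
    return LPSolution(x_star=vertices.vertices[int(np.argmax(scores))],
                      objective=best, all_optima=VertexSet(optima))


def grade_solution(problem: AllocationLP, x: Sequence[float],
                   tol: float = 1e-6) -> GradeReport:
    """Classify a proposed allocation against the solved optimum.

    ``tol`` is the optimality tolerance in objective units; proposed
    answers are typically fractions with two decimals, so the default is
    generous but safe.  ``gap`` = optimum - c . x (negative gaps cannot
    occur for feasible x).
    """
    x = np.asarray(x, dtype=float)
    sol = solve(problem)
    feasible = contains(problem.polytope, x, tol=tol)
    value = float(problem.c @ x)
    gap = sol.objective - value
    return GradeReport(feasible=feasible,
                       optimal=bool(feasible and gap <= tol),
                       gap=gap)
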