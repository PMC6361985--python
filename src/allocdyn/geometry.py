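"""Implicit decision spaces: box-on-simplex polytopes and hull membership.

Every decision space arising in the allocation tasks is the intersection of
an axis-aligned box with the supply hyperplane:

    P = { x in R^m : l <= x <= u,  x >= 0,  sum_j x_j = s }.

A group's *implicit* decision space is the polytope cut from the simplex by
the coordinate-wise min and max of the members' initial allocation opinions;
an experiment may additionally impose an explicit box (intersection of the
two).  The H-representation is kept as bounds plus the one equality, which
makes membership, emptiness and exact vertex enumeration straightforward for
the small dimensions (m <= 6) that occur.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .dynamics import OpinionArray

__all__ = [
    "DecisionPolytope",
    "VertexSet",
    "contains",
    "enumerate_vertices",
    "hull_contains",
    "intersect",
    "is_empty",
    "minmax_cuts",
]

#: Default membership tolerance, in allocation units (opinions are recorded
#: as integer percentages, so 1e-6 is strict but safe).
MEMBERSHIP_TOL = 1e-6

#: Vertex deduplication tolerance (max-norm); pin patterns can coincide at corners.
DEDUP_TOL = 1e-8


@dataclass(frozen=True)
class DecisionPolytope:
    """H-representation of a box cut by the supply hyperplane.

    Lower bounds are clipped at 0 on construction (allocations are
    non-negative).  The polytope may be empty, e.g. after intersecting
    disjoint boxes; use :func:`is_empty`.
    """

    supply: float
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.maximum(np.asarray(self.lower, dtype=float), 0.0)
        upper = np.asarray(self.upper, dtype=float)
        if lower.shape != upper.shape or lower.ndim != 1:
            raise ValueError("lower and upper must be 1-d vectors of equal length")
        if self.supply <= 0:
            raise ValueError("supply must be positive")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def m(self) -> int:
        return self.lower.size


@dataclass(frozen=True)
class VertexSet:
    """Deduplicated vertices of a decision polytope."""

    vertices: np.ndarray  # (k, m)

    def __len__(self) -> int:
        return self.vertices.shape[0]

    def __iter__(self):
        return iter(self.vertices)


def minmax_cuts(X0) -> DecisionPolytope:
    """The implicit polytope cut by a group's extremal initial opinions.

    l_j (u_j) is the minimum (maximum) over members of the initial opinion on
    dimension j; by construction every member's initial opinion lies in the
    resulting polytope.
    """
    if isinstance(X0, OpinionArray):
        if not X0.simplex_constrained:
            raise ValueError("minmax_cuts requires simplex-constrained opinions")
        X, supply = X0.X, X0.supply
    else:
        X = np.atleast_2d(np.asarray(X0, dtype=float))
        supply = float(X[0].sum())
    return DecisionPolytope(supply=supply, lower=X.min(axis=0), upper=X.max(axis=0))


def intersect(p1: DecisionPolytope, p2: DecisionPolytope) -> DecisionPolytope:
    """Intersection of two decision spaces over the same simplex; may be empty."""
    if p1.m != p2.m:
        raise ValueError(f"dimension mismatch: {p1.m} vs {p2.m}")
    if abs(p1.supply - p2.supply) > 1e-9 * max(1.0, p1.supply):
        raise ValueError(f"supply mismatch: {p1.supply} vs {p2.supply}")
    return DecisionPolytope(supply=p1.supply,
                            lower=np.maximum(p1.lower, p2.lower),
                            upper=np.minimum(p1.upper, p2.upper))


def is_empty(p: DecisionPolytope) -> bool:
    """A box-on-simplex polytope is nonempty iff l <= u and sum l <= s <= sum u."""
    if np.any(p.lower > p.upper):
        return True
    return bool(p.lower.sum() > p.supply or p.upper.sum() < p.supply)


def contains(p: DecisionPolytope, x: Sequence[float],
             tol: float = MEMBERSHIP_TOL) -> bool:
    """Whether point x lies on the decision space within tolerance ``tol``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (p.m,):
        raise ValueError(f"point has shape {x.shape}, expected ({p.m},)")
    if np.any(x < p.lower - tol) or np.any(x > p.upper + tol):
        return False
    return bool(abs(x.sum() - p.supply) <= tol)


def enumerate_vertices(p: DecisionPolytope) -> VertexSet:
    """All vertices of {l <= x <= u, sum x = s}, exactly.

    A vertex of this polytope has m - 1 coordinates pinned at a lower or
    upper bound with the remaining coordinate determined by the supply
    equality.  All m * 2^(m-1) pin patterns are enumerated, infeasible
    solutions discarded, and coincident corners deduplicated (max-norm,
    1e-8).  Intended for m <= 6.
    """
    if is_empty(p):
        raise ValueError("cannot enumerate vertices of an empty polytope")
    m = p.m
    found: list[np.ndarray] = []
    for free in range(m):
        pinned = [j for j in range(m) if j != free]
        for pattern in product((0, 1), repeat=m - 1):
            x = np.empty(m)
            for j, side in zip(pinned, pattern):
                x[j] = p.upper[j] if side else p.lower[j]
            x[free] = p.supply - x[pinned].sum()
            if x[free] < p.lower[free] - DEDUP_TOL or x[free] > p.upper[free] + DEDUP_TOL:
                continue
            x[free] = min(max(x[free], p.lower[free]), p.upper[free])
            if not any(np.max(np.abs(x - v)) <= DEDUP_TOL for v in found):
                found.append(x)
    return VertexSet(np.array(found))


def hull_contains(points, x: Sequence[float], tol: float = MEMBERSHIP_TOL) -> bool:
    """Whether x lies in the convex hull of ``points`` (small point sets).

    Solves the linear feasibility problem over the barycentric weights:
    minimize the max-norm deviation t subject to
    ``|P^T lam - x| <= t, sum lam = 1, lam >= 0`` and accepts when the
    optimal t is at most ``tol``.  Exact (up to LP solver precision) for the
    group-sized instances (<= 8 points) this is used on.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    x = np.asarray(x, dtype=float)
    k, m = P.shape
    if not 1 <= k <= 8:
        raise ValueError("hull_contains is intended for 1-8 points")
    if x.shape != (m,):
        raise ValueError(f"point has shape {x.shape}, expected ({m},)")
    # variables: lam (k), t (1); minimize t
    c = np.zeros(k + 1)
    c[-1] = 1.0
    # P^T lam - x <= t  and  x - P^T lam <= t
    A_ub = np.block([[P.T, -np.ones((m, 1))],
                     [-P.T, -np.ones((m, 1))]])
    b_ub = np.concatenate([x, -x])
    A_eq = np.zeros((1, k + 1))
    A_eq[0, :k] = 1.0
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=[1.0],
                  bounds=[(0, None)] * k + [(0, None)], method="highs")
    if not res.success:
        return False
    return bool(res.fun <= tol)
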