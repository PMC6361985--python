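"""Friedkin-Johnsen and DeGroot opinion dynamics on multidimensional opinions.

The Friedkin-Johnsen (FJ) model updates a group's n x m opinion array by

    X(k+1) = A W X(k) + (I - A) X(0),    k = 0, 1, ...

where W is a row-stochastic matrix of interpersonal influence weights and
A = diag(a_11, ..., a_nn) with a_ii = 1 - w_ii the susceptibility of member i
to interpersonal influence (equivalently, 1 - a_ii is the anchorage on the
member's initial opinion).  When every a_ii < 1 the map is a contraction and
the settled opinions are

    X_hat = V X(0),    V = (I - A W)^{-1} (I - A),

with V row-stochastic: entry v_ij is the total (direct plus indirect)
influence of member j's initial opinion on member i's settled opinion.  Each
row of X_hat is therefore a convex combination of the rows of X(0), which is
what keeps settled allocation opinions inside the group's implicit decision
space.  The DeGroot model (pure iterative averaging, X(k+1) = W X(k)) is the
A = I special case.

The module exposes both the functional operations (``fj_step``,
``fj_iterate``, ``total_influence_matrix``, ``fj_equilibrium``, ...) and a
statsmodels-style pair :class:`FriedkinJohnsenModel` / :class:`FJResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "ROW_SUM_TOL",
    "ConsensusCertificate",
    "FJResults",
    "FriedkinJohnsenModel",
    "InfluenceSystem",
    "OpinionArray",
    "PredictionResult",
    "SingularInfluenceError",
    "Trajectory",
    "degroot_consensus_certificate",
    "degroot_iterate",
    "fj_equilibrium",
    "fj_iterate",
    "fj_step",
    "influence_from_chips",
    "total_influence_matrix",
    "weights_from_chips",
]

#: Tolerance for row-stochasticity / simplex row-sum validation.
ROW_SUM_TOL = 1e-9

#: Reciprocal-condition threshold below which I - AW is treated as singular.
RCOND_THRESHOLD = 1e-12

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 100_000


class SingularInfluenceError(np.linalg.LinAlgError):
    """I - AW is singular or near-singular; use the iterative path instead."""


@dataclass(frozen=True)
class InfluenceSystem:
    """Row-stochastic influence weights W with derived susceptibilities.

    Parameters
    ----------
    W : (n, n) array
        w_ij is the weight member i places on member j's displayed opinion.
        Rows must sum to 1 (tolerance 1e-9) with entries in [0, 1].

    The susceptibility vector is always derived: ``a_ii = 1 - w_ii``.  It is
    exposed as the :attr:`A` property (diagonal matrix) and :attr:`a` (vector)
    and never stored independently.
    """

    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"W must be square, got shape {W.shape}")
        if np.any(W < -ROW_SUM_TOL) or np.any(W > 1 + ROW_SUM_TOL):
            raise ValueError("influence weights must lie in [0, 1]")
        row_sums = W.sum(axis=1)
        bad = np.flatnonzero(np.abs(row_sums - 1.0) > ROW_SUM_TOL)
        if bad.size:
            raise ValueError(
                f"rows {bad.tolist()} of W do not sum to 1 "
                f"(sums {row_sums[bad].tolist()})"
            )
        object.__setattr__(self, "W", W)

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def a(self) -> np.ndarray:
        """Susceptibility vector, a_ii = 1 - w_ii."""
        return 1.0 - np.diag(self.W)

    @property
    def A(self) -> np.ndarray:
        """Susceptibility diagonal matrix diag(1 - w_ii)."""
        return np.diag(self.a)


@dataclass(frozen=True)
class OpinionArray:
    """An n x m array of opinions, optionally constrained to the supply simplex.

    For allocation issues each row is a distribution of a fixed supply ``s``
    over m options: entries non-negative and summing to s (tolerance 1e-9).
    Constraint-task opinions (min/max bounds recorded as 2m values per member)
    set ``simplex_constrained=False`` and are not validated against the
    simplex.
    """

    X: np.ndarray
    supply: float = 100.0
    simplex_constrained: bool = True

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.supply <= 0:
            raise ValueError("supply must be positive")
        if self.simplex_constrained:
            if np.any(X < -ROW_SUM_TOL):
                raise ValueError("simplex-constrained opinions must be non-negative")
            sums = X.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - self.supply) > ROW_SUM_TOL * max(1.0, self.supply))
            if bad.size:
                raise ValueError(
                    f"rows {bad.tolist()} do not sum to supply {self.supply} "
                    f"(sums {sums[bad].tolist()})"
                )
        object.__setattr__(self, "X", X)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    def replace_values(self, X: np.ndarray) -> "OpinionArray":
        """Same constraints, new values (revalidated)."""
        return OpinionArray(X, supply=self.supply,
                            simplex_constrained=self.simplex_constrained)


@dataclass
class Trajectory:
    """An iterated opinion sequence X(0), X(1), ... with convergence info."""

    states: list
    converged: bool
    final_residual: float

    @property
    def iterations(self) -> int:
        return len(self.states) - 1

    @property
    def final(self) -> OpinionArray:
        return self.states[-1]


@dataclass
class PredictionResult:
    """Equilibrium opinions, total influence and predicted net changes."""

    X_hat: np.ndarray
    V: Optional[np.ndarray]
    changes: np.ndarray
    method: Literal["closed_form", "iterative"]


def weights_from_chips(chips: Sequence[float], self_index: int) -> np.ndarray:
    """One row of W from a member's 100-chip allocation.

    Subjects distribute 100 chips across group members (self included at
    position ``self_index``) to report relative influence on their final
    answer.  The construct is a relative weight distribution, so totals that
    are not exactly 100 (arithmetic slips) are renormalized by their own
    total; an all-zero report is unusable and rejected.
    """
    chips = np.asarray(chips, dtype=float)
    if chips.ndim != 1:
        raise ValueError("chips must be a 1-d vector")
    if not 0 <= self_index < chips.size:
        raise ValueError(f"self_index {self_index} out of range for {chips.size} members")
    if np.any(chips < 0):
        raise ValueError("chip counts must be non-negative")
    total = chips.sum()
    if total <= 0:
        raise ValueError("all-zero chip allocation: unusable self-report")
    return chips / total


def influence_from_chips(chips: np.ndarray) -> InfluenceSystem:
    """Build the full influence system from an n x n chip matrix (row i = member i)."""
    chips = np.asarray(chips, dtype=float)
    if chips.ndim != 2 or chips.shape[0] != chips.shape[1]:
        raise ValueError(f"chip matrix must be square, got {chips.shape}")
    W = np.vstack([weights_from_chips(row, i) for i, row in enumerate(chips)])
    return InfluenceSystem(W)


def _coerce_opinions(X) -> OpinionArray:
    if isinstance(X, OpinionArray):
        return X
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return OpinionArray(X, supply=max(float(X[0].sum()), 1e-300),
                        simplex_constrained=False)


def fj_step(X_k: OpinionArray, system: InfluenceSystem,
            X_0: OpinionArray) -> OpinionArray:
    """One Friedkin-Johnsen update: A W X(k) + (I - A) X(0)."""
    Xk, X0 = _coerce_opinions(X_k), _coerce_opinions(X_0)
    if Xk.X.shape != X0.X.shape:
        raise ValueError(f"shape mismatch: X(k) {Xk.X.shape} vs X(0) {X0.X.shape}")
    if Xk.n != system.n:
        raise ValueError(f"shape mismatch: {Xk.n} members vs {system.n}x{system.n} W")
    a = system.a[:, None]
    X_next = a * (system.W @ Xk.X) + (1.0 - a) * X0.X
    return X0.replace_values(X_next)


def fj_iterate(X_0, system: InfluenceSystem, max_iter: int = DEFAULT_MAX_ITER,
               tol: float = DEFAULT_TOL) -> Trajectory:
    """Iterate the FJ update from X(0) until the one-step change falls below tol.

    Non-convergence within ``max_iter`` is reported via the ``converged``
    flag, not raised: with some a_ii = 1 and a periodic influence graph the
    iteration can oscillate, and the trajectory itself is then the object of
    interest.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    X0 = _coerce_opinions(X_0)
    states = [X0]
    residual = np.inf
    for _ in range(max_iter):
        X_next = fj_step(states[-1], system, X0)
        residual = float(np.max(np.abs(X_next.X - states[-1].X)))
        states.append(X_next)
        if residual < tol:
            return Trajectory(states, converged=True, final_residual=residual)
    return Trajectory(states, converged=False, final_residual=residual)


def degroot_iterate(X_0, W: np.ndarray, max_iter: int = DEFAULT_MAX_ITER,
                    tol: float = DEFAULT_TOL) -> Trajectory:
    """Pure iterative averaging X(k+1) = W X(k), the A = I special case."""
    system = InfluenceSystem(np.asarray(W, dtype=float))
    X0 = _coerce_opinions(X_0)
    states = [X0]
    residual = np.inf
    for _ in range(max_iter):
        X_next = X0.replace_values(system.W @ states[-1].X)
        residual = float(np.max(np.abs(X_next.X - states[-1].X)))
        states.append(X_next)
        if residual < tol:
            return Trajectory(states, converged=True, final_residual=residual)
    return Trajectory(states, converged=False, final_residual=residual)


def total_influence_matrix(system: InfluenceSystem) -> np.ndarray:
    """Total influence matrix V = (I - AW)^{-1} (I - A).

    v_ij is the total (direct and indirect) weight of member j's initial
    opinion in member i's settled opinion; V is row-stochastic whenever it
    exists.  Raises :class:`SingularInfluenceError` when I - AW is singular or
    near-singular (reciprocal condition < 1e-12), directing the caller to the
    iterative path.
    """
    n = system.n
    a = system.a
    M = np.eye(n) - a[:, None] * system.W
    rcond = _rcond(M)
    if rcond < RCOND_THRESHOLD:
        raise SingularInfluenceError(
            f"I - AW is singular or near-singular (rcond ~ {rcond:.2e}); "
            "use fj_iterate instead"
        )
    V = np.linalg.solve(M, np.diag(1.0 - a))
    return V


def _rcond(M: np.ndarray) -> float:
    try:
        return 1.0 / np.linalg.cond(M, p=None)
    except np.linalg.LinAlgError:
        return 0.0


def fj_equilibrium(X_0, system: InfluenceSystem, max_iter: int = DEFAULT_MAX_ITER,
                   tol: float = DEFAULT_TOL) -> PredictionResult:
    """Settled opinions X_hat = V X(0) and predicted net changes X_hat - X(0).

    Uses the closed form when I - AW is well conditioned; otherwise falls
    back to iteration and reports ``method="iterative"``.  The singularity
    error propagates only if the iteration also fails to converge.
    """
    X0 = _coerce_opinions(X_0)
    if X0.n != system.n:
        raise ValueError(f"shape mismatch: {X0.n} members vs {system.n}x{system.n} W")
    try:
        V = total_influence_matrix(system)
    except SingularInfluenceError:
        traj = fj_iterate(X0, system, max_iter=max_iter, tol=tol)
        if not traj.converged:
            raise
        X_hat = traj.final.X
        return PredictionResult(X_hat=X_hat, V=None, changes=X_hat - X0.X,
                                method="iterative")
    X_hat = V @ X0.X
    return PredictionResult(X_hat=X_hat, V=V, changes=X_hat - X0.X,
                            method="closed_form")


@dataclass
class ConsensusCertificate:
    """Sufficient-condition certificate for DeGroot consensus.

    ``aperiodic`` is True when certified by the sufficient condition
    w_ii > 0 for all i, and None ("undetermined") otherwise; consensus is
    guaranteed only when a globally reachable node exists *and* aperiodicity
    is certified.
    """

    consensus_guaranteed: bool
    reachable_node: Optional[int]
    aperiodic: Optional[bool]


def degroot_consensus_certificate(W: np.ndarray) -> ConsensusCertificate:
    """Check the DeGroot consensus conditions on the influence graph of W.

    The directed influence graph has an arc i -> j whenever w_ij > 0 (member
    i weights member j).  Consensus under pure iterative averaging is
    guaranteed when some node is reachable from every node along arcs (a
    globally reachable node) and the graph is aperiodic; aperiodicity is
    certified here only by the sufficient condition w_ii > 0 for all i.
    """
    system = InfluenceSystem(np.asarray(W, dtype=float))
    W = system.W
    n = system.n
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if W[i, j] > 0:
                G.add_edge(i, j)
    reachable_node: Optional[int] = None
    for j in range(n):
        # j globally reachable <=> every i reaches j <=> all nodes are
        # ancestors of j (or j itself)
        if len(nx.ancestors(G, j)) == n - 1:
            reachable_node = j
            break
    aperiodic: Optional[bool] = True if np.all(np.diag(W) > 0) else None
    guaranteed = reachable_node is not None and aperiodic is True
    return ConsensusCertificate(consensus_guaranteed=guaranteed,
                                reachable_node=reachable_node,
                                aperiodic=aperiodic)


class FriedkinJohnsenModel:
    """Friedkin-Johnsen influence model for one group's allocation task.

    Built from the group's measured constructs — the initial opinion array
    X(0) and the influence matrix W (directly or via 100-chip self-reports) —
    with no free parameters to estimate: ``fit()`` deterministically computes
    the settled opinions, total influence matrix and predicted net opinion
    changes, returned as an :class:`FJResults`.

    Examples
    --------
    >>> model = FriedkinJohnsenModel([[0.0], [100.0]],
    ...                              [[0.5, 0.5], [0.5, 0.5]],
    ...                              simplex_constrained=False)
    >>> res = model.fit()
    >>> res.equilibrium
    array([[25.],
           [75.]])
    """

    def __init__(self, initial_opinions, influence, supply: float = 100.0,
                 simplex_constrained: bool = True):
        if isinstance(initial_opinions, OpinionArray):
            self.X0 = initial_opinions
        else:
            self.X0 = OpinionArray(initial_opinions, supply=supply,
                                   simplex_constrained=simplex_constrained)
        self.system = (influence if isinstance(influence, InfluenceSystem)
                       else InfluenceSystem(influence))
        if self.X0.n != self.system.n:
            raise ValueError(
                f"{self.X0.n} opinion rows but {self.system.n}x{self.system.n} W")

    @classmethod
    def from_chips(cls, initial_opinions, chips, supply: float = 100.0,
                   simplex_constrained: bool = True) -> "FriedkinJohnsenModel":
        """Build the model from raw 100-chip self-reports (n x n matrix)."""
        return cls(initial_opinions, influence_from_chips(chips), supply=supply,
                   simplex_constrained=simplex_constrained)

    @classmethod
    def from_group(cls, group) -> "FriedkinJohnsenModel":
        """Build the model from a :class:`~allocdyn.synthetic.GroupRecord`."""
        return cls(group.X0, influence_from_chips(group.chips))

    def fit(self, method: str = "auto", max_iter: int = DEFAULT_MAX_ITER,
            tol: float = DEFAULT_TOL) -> "FJResults":
        """Compute the equilibrium prediction.

        method : "auto" (closed form with iterative fallback), "closed_form",
        or "iterative".
        """
        if method == "auto":
            pred = fj_equilibrium(self.X0, self.system, max_iter=max_iter, tol=tol)
        elif method == "closed_form":
            V = total_influence_matrix(self.system)
            X_hat = V @ self.X0.X
            pred = PredictionResult(X_hat, V, X_hat - self.X0.X, "closed_form")
        elif method == "iterative":
            traj = fj_iterate(self.X0, self.system, max_iter=max_iter, tol=tol)
            if not traj.converged:
                raise SingularInfluenceError(
                    f"iteration did not converge in {max_iter} steps "
                    f"(residual {traj.final_residual:.2e})")
            X_hat = traj.final.X
            pred = PredictionResult(X_hat, None, X_hat - self.X0.X, "iterative")
        else:
            raise ValueError(f"unknown method {method!r}")
        return FJResults(self, pred)

    def simulate(self, max_iter: int = DEFAULT_MAX_ITER,
                 tol: float = DEFAULT_TOL) -> Trajectory:
        """The full opinion trajectory under iterated FJ updates."""
        return fj_iterate(self.X0, self.system, max_iter=max_iter, tol=tol)


class FJResults:
    """Results of a fitted :class:`FriedkinJohnsenModel`."""

    def __init__(self, model: FriedkinJohnsenModel, prediction: PredictionResult):
        self.model = model
        self._pred = prediction

    @property
    def equilibrium(self) -> np.ndarray:
        """Settled opinion array X_hat (n x m)."""
        return self._pred.X_hat

    @property
    def total_influence(self) -> Optional[np.ndarray]:
        """Row-stochastic V mapping initial to settled opinions (closed form only)."""
        return self._pred.V

    @property
    def changes(self) -> np.ndarray:
        """Predicted net opinion changes X_hat - X(0)."""
        return self._pred.changes

    @property
    def method(self) -> str:
        return self._pred.method

    @property
    def prediction(self) -> PredictionResult:
        return self._pred

    def decision_space(self):
        """The group's implicit min-max polytope cut by X(0)."""
        from .geometry import minmax_cuts
        return minmax_cuts(self.model.X0)

    def in_decision_space(self, tol: float = 1e-6) -> np.ndarray:
        """Per-member flag: settled opinion inside the implicit polytope."""
        from .geometry import contains
        poly = self.decision_space()
        return np.array([contains(poly, row, tol=tol) for row in self.equilibrium])

    def consensus(self, delta: float = 1e-6) -> bool:
        """Whether settled opinions coincide within delta on every dimension."""
        spread = np.ptp(self.equilibrium, axis=0)
        return bool(np.max(spread) <= delta)

    def summary(self) -> str:
        """Plain-text summary of the prediction."""
        X0, Xh = self.model.X0.X, self.equilibrium
        n, m = X0.shape
        lines = [
            "Friedkin-Johnsen influence model",
            "=" * 48,
            f"members: {n}    dimensions: {m}    supply: {self.model.X0.supply:g}",
            f"solution method: {self.method}",
            f"consensus (delta=1e-6): {self.consensus()}",
            "",
            "member   a_ii   initial -> settled",
        ]
        a = self.model.system.a
        for i in range(n):
            init = ", ".join(f"{v:8.3f}" for v in X0[i])
            fin = ", ".join(f"{v:8.3f}" for v in Xh[i])
            lines.append(f"{i:>6} {a[i]:6.3f}   [{init}] -> [{fin}]")
        if self.total_influence is not None:
            lines += ["", "total influence V (rows: members; v_ij = influence of j on i):"]
            for row in self.total_influence:
                lines.append("   " + "  ".join(f"{v:6.4f}" for v in row))
        return "\n".join(lines)
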