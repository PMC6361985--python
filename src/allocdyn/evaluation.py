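"""Observed-versus-predicted evaluation of the influence model.

The evaluation criterion is the strength of the linear correspondence
between stacked observed and predicted settled opinions (and net opinion
changes): opinion matrices are column-vectorized, concatenated across the
cohort's groups, and summarized by the product-moment correlation rho with a
two-sided t-test p-value.  Alongside the correlations the summary reports
the fraction of members whose observed final position lies on their group's
implicit decision space, and the count of groups reaching consensus.  A
two-sided Fisher exact test on a 2x2 contingency table supports the
independence question in the two-part (constraints-then-ideals) task.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import OpinionArray
from .geometry import DecisionPolytope, contains, intersect, minmax_cuts

__all__ = [
    "EvaluationSummary",
    "UndefinedCorrelationError",
    "cohort_records",
    "consensus_reached",
    "evaluate_cohort",
    "fisher_exact_2x2",
    "pearson_with_p",
    "stack_columns",
]


class UndefinedCorrelationError(ValueError):
    """Correlation undefined: a stacked vector has (near) zero variance."""


def stack_columns(X: np.ndarray) -> np.ndarray:
    """Column vectorization: concatenate the columns of X in dimension order."""
    return np.asarray(X, dtype=float).flatten(order="F")


def pearson_with_p(obs: Sequence[float], pred: Sequence[float]) -> dict:
    """Product-moment rho with two-sided p from the t-test on n - 2 df.

    Raises :class:`UndefinedCorrelationError` when either vector has zero
    variance (the correlation is then meaningless and must not silently
    become 0 or NaN).
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("obs and pred must be 1-d vectors of equal length")
    n = obs.size
    if n < 3:
        raise ValueError("need at least 3 observations for a p-value")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise UndefinedCorrelationError("zero variance in stacked vector")
    rho, p = stats.pearsonr(obs, pred)
    return {"rho": float(rho), "p": float(p), "n": n}


def consensus_reached(X_final, delta: float = 1e-6) -> bool:
    """Whether all members' final positions coincide within delta per dimension.

    The default delta treats only identical recorded positions as consensus
    (members who agreed record the same numbers); raise it for noisy
    synthetic observations.
    """
    X = X_final.X if isinstance(X_final, OpinionArray) else np.atleast_2d(
        np.asarray(X_final, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("consensus needs at least 2 members")
    return bool(np.max(np.ptp(X, axis=0)) <= delta)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table, by full enumeration.

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities that do not exceed the observed table's
    probability (ties included up to a 1e-7 relative slack, so float-level
    ties behave deterministically).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if not np.all(t == np.floor(t)):
        raise ValueError("counts must be integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, c1, N = a + b, a + c, a + b + c + d
    if N == 0:
        return 1.0
    support = np.arange(max(0, c1 - (N - r1)), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, N, c1, r1)
    p_obs = stats.hypergeom.pmf(a, N, c1, r1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


@dataclass
class EvaluationSummary:
    """Pooled cohort-level evaluation of the influence-model predictions."""

    rho_final: float
    p_final: float
    rho_changes: Optional[float]
    p_changes: Optional[float]
    n_stacked: int
    frac_in_space: float
    n_members: int
    consensus_groups: int
    total_groups: int
    changes_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "rho_final": self.rho_final,
            "p_final": self.p_final,
            "rho_changes": self.rho_changes,
            "p_changes": self.p_changes,
            "n_stacked": self.n_stacked,
            "frac_in_space": self.frac_in_space,
            "n_members": self.n_members,
            "consensus_groups": self.consensus_groups,
            "total_groups": self.total_groups,
            "changes_defined": self.changes_defined,
        }


def _group_space(group, box: Optional[DecisionPolytope]) -> Optional[DecisionPolytope]:
    """Implicit min-max polytope, intersected with an explicit box if given."""
    if not group.X0.simplex_constrained:
        return None
    poly = minmax_cuts(group.X0)
    if box is not None:
        poly = intersect(poly, box)
    return poly


def _member_in_space(group, x: np.ndarray, box, tol: float) -> bool:
    poly = _group_space(group, box)
    if poly is not None:
        return contains(poly, x, tol=tol)
    # constraint-task (non-simplex) opinions: coordinate-wise min-max box only
    lower = group.X0.X.min(axis=0)
    upper = group.X0.X.max(axis=0)
    return bool(np.all(x >= lower - tol) and np.all(x <= upper + tol))


def evaluate_cohort(groups, box: Optional[DecisionPolytope] = None,
                    delta: float = 1e-6, tol: float = 1e-6) -> EvaluationSummary:
    """Pool observed-vs-predicted comparisons over a cohort.

    Parameters
    ----------
    groups : sequence of (GroupRecord, PredictionResult)
        Every group must carry observed finals.
    box : DecisionPolytope, optional
        Explicit experiment-wide decision space; the implicit per-group
        polytope is intersected with it before membership testing.
    delta : float
        Consensus tolerance on observed finals.
    tol : float
        Membership tolerance for the in-space fraction.
    """
    groups = list(groups)
    if not groups:
        raise ValueError("empty cohort")
    obs_stack, pred_stack = [], []
    obs_chg, pred_chg = [], []
    in_space, n_members = 0, 0
    consensus_count = 0
    for group, pred in groups:
        if group.observed_final is None:
            raise ValueError(f"group {group.group_id!r} has no observed finals")
        obs = group.observed_final.X
        obs_stack.append(stack_columns(obs))
        pred_stack.append(stack_columns(pred.X_hat))
        obs_chg.append(stack_columns(obs - group.X0.X))
        pred_chg.append(stack_columns(pred.changes))
        for i in range(group.n):
            n_members += 1
            if _member_in_space(group, obs[i], box, tol):
                in_space += 1
        if consensus_reached(group.observed_final, delta=delta):
            consensus_count += 1
    obs_v, pred_v = np.concatenate(obs_stack), np.concatenate(pred_stack)
    final = pearson_with_p(obs_v, pred_v)
    try:
        chg = pearson_with_p(np.concatenate(obs_chg), np.concatenate(pred_chg))
        rho_c, p_c, defined = chg["rho"], chg["p"], True
    except UndefinedCorrelationError:
        # e.g. no member changed opinion at all; flagged, not NaN-propagated
        rho_c, p_c, defined = None, None, False
    return EvaluationSummary(
        rho_final=final["rho"], p_final=final["p"],
        rho_changes=rho_c, p_changes=p_c,
        n_stacked=final["n"],
        frac_in_space=in_space / n_members,
        n_members=n_members,
        consensus_groups=consensus_count,
        total_groups=len(groups),
        changes_defined=defined,
    )


def cohort_records(groups, box: Optional[DecisionPolytope] = None,
                   tol: float = 1e-6) -> pd.DataFrame:
    """Flat per-member table: initial/observed/predicted per dimension + in_space."""
    rows = []
    for group, pred in groups:
        obs = None if group.observed_final is None else group.observed_final.X
        for i in range(group.n):
            rec = {"group_id": group.group_id, "member": i}
            for j in range(group.m):
                rec[f"initial_{j}"] = group.X0.X[i, j]
                rec[f"predicted_{j}"] = pred.X_hat[i, j]
                rec[f"observed_{j}"] = np.nan if obs is None else obs[i, j]
            rec["in_space"] = (
                _member_in_space(group, obs[i], box, tol) if obs is not None else np.nan)
            rows.append(rec)
    return pd.DataFrame(rows)
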