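"""Synthetic cohorts emulating the laboratory allocation tasks.

The subject-level data behind the allocation experiments are not publicly
deposited, so this module generates cohorts with the same statistical
structure: groups of 3-4 members; 3- or 4-dimensional allocation issues with
supply 100 (percentages); heterogeneous simplex-valued initial opinions
drawn from a Dirichlet law; influence weights measured through 100-chip
self-reports with a dominant self-weight; observed finals equal to the
Friedkin-Johnsen equilibrium plus bounded observation noise projected back
to the simplex; and the two-part task (consensus on min/max constraints,
then on an ideal position inside them).

Ground truth is the influence model itself — noise enters the observations
only, never the weights — so the full generate -> predict -> evaluate
pipeline recovers a perfect correspondence as the noise scale goes to zero.
All randomness flows through numpy Generators spawned from a single seed;
per-group streams are independent ``SeedSequence`` children.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np

from .dynamics import OpinionArray, fj_equilibrium, influence_from_chips
from .geometry import DecisionPolytope, is_empty

__all__ = [
    "GroupRecord",
    "SyntheticConfig",
    "generate_cohort",
    "generate_group",
    "generate_two_part_group",
    "simulate_observed_finals",
]

_MAX_REJECTION = 100_000


@dataclass
class GroupRecord:
    """One group's task: initial opinions, chip self-reports, observed finals."""

    group_id: str
    X0: OpinionArray
    chips: np.ndarray  # (n, n) non-negative integers, row i = member i's report
    observed_final: Optional[OpinionArray] = None
    experiment_kind: str = "unconstrained"

    def __post_init__(self) -> None:
        chips = np.asarray(self.chips)
        if chips.shape != (self.X0.n, self.X0.n):
            raise ValueError(
                f"chips shape {chips.shape} does not match {self.X0.n} members")
        if np.any(chips < 0):
            raise ValueError("chip counts must be non-negative")
        self.chips = chips.astype(int)
        if self.observed_final is not None and (
                self.observed_final.X.shape != self.X0.X.shape):
            raise ValueError("observed finals must match the initial array's shape")

    @property
    def n(self) -> int:
        return self.X0.n

    @property
    def m(self) -> int:
        return self.X0.m

    @property
    def supply(self) -> float:
        return self.X0.supply


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults emulate the laboratory conditions.

    alpha : Dirichlet concentration for initial opinions (per dimension).
        The default 4.0 gives heterogeneous but non-extreme preferences
        (per-coordinate spread of roughly 13 percentage points at m = 3).
    self_weight_law : (lo, hi) for uniform integer self-chips, or a callable
        ``rng -> int``.  Default (30, 80): most subjects retain a dominant
        self-weight.
    noise_sd : observation noise on recorded finals, in allocation units.
        Default 2.0 — answers are recorded as integer percentages, so noise
        on the order of a couple of points.
    box : optional explicit decision space (given-constraints tasks);
        initial opinions are rejection-resampled into it.
    member_sizes : group sizes drawn uniformly; default {3, 4}.
    """

    n_groups: int = 23
    m: int = 3
    supply: float = 100.0
    alpha: Union[float, Sequence[float]] = 4.0
    self_weight_law: Union[tuple, Callable] = (30, 80)
    noise_sd: float = 2.0
    seed: int = 0
    box: Optional[DecisionPolytope] = None
    member_sizes: tuple = (3, 4)
    experiment_kind: str = "unconstrained"
    share_chips: bool = True

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if self.m < 2:
            raise ValueError("need at least 2 allocation dimensions")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        alpha = np.broadcast_to(np.asarray(self.alpha, dtype=float), (self.m,)).copy()
        if np.any(alpha <= 0):
            raise ValueError("alpha must be positive")
        self.alpha = alpha
        if self.box is not None and is_empty(self.box):
            raise ValueError("explicit box is infeasible for the supply")


def _draw_self_chips(law, rng: np.random.Generator) -> int:
    if callable(law):
        return int(law(rng))
    lo, hi = law
    return int(rng.integers(lo, hi + 1))


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative weights to integers summing exactly to ``total``."""
    if total == 0 or weights.sum() == 0:
        out = np.zeros(weights.size, dtype=int)
        out[: total] = 1  # degenerate: spread single units
        return out
    scaled = weights / weights.sum() * total
    base = np.floor(scaled).astype(int)
    short = total - base.sum()
    order = np.argsort(-(scaled - base))
    base[order[:short]] += 1
    return base


def _draw_chips(n: int, law, rng: np.random.Generator) -> np.ndarray:
    """An n x n integer chip matrix, each row summing to exactly 100."""
    chips = np.zeros((n, n), dtype=int)
    for i in range(n):
        self_chips = min(_draw_self_chips(law, rng), 100)
        others = rng.dirichlet(np.ones(n - 1))
        row = _largest_remainder(others, 100 - self_chips)
        chips[i] = np.insert(row, i, self_chips)
    return chips


def _draw_simplex_rows(n: int, config: SyntheticConfig,
                       rng: np.random.Generator) -> np.ndarray:
    rows = np.empty((n, config.m))
    for i in range(n):
        for attempt in range(_MAX_REJECTION):
            x = rng.dirichlet(config.alpha) * config.supply
            if config.box is None or (
                    np.all(x >= config.box.lower) and np.all(x <= config.box.upper)):
                rows[i] = x
                break
        else:
            raise RuntimeError(
                "rejection sampling failed: explicit box is too tight for alpha")
    return rows


def generate_group(config: SyntheticConfig, n: Optional[int] = None,
                   rng: Optional[np.random.Generator] = None,
                   group_id: str = "g0") -> GroupRecord:
    """One synthetic group: simplex initial opinions + 100-chip reports."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n is None:
        n = int(rng.choice(config.member_sizes))
    if n < 2:
        raise ValueError("need at least 2 members")
    X0 = OpinionArray(_draw_simplex_rows(n, config, rng), supply=config.supply)
    chips = _draw_chips(n, config.self_weight_law, rng)
    return GroupRecord(group_id=group_id, X0=X0, chips=chips,
                       experiment_kind=config.experiment_kind)


def simulate_observed_finals(group: GroupRecord, noise_sd: float,
                             rng: Optional[np.random.Generator] = None,
                             seed: Optional[int] = None) -> OpinionArray:
    """Observed finals = model equilibrium + Gaussian noise, reprojected.

    The projection is clip-and-rescale: negative entries are clipped to 0
    and each row rescaled to sum to the supply (a modeling choice that keeps
    observations positive and on the simplex).  At ``noise_sd = 0`` the
    equilibrium is returned exactly.  Constraint-task (non-simplex) opinions
    are clipped to [0, supply] and each (min, max) pair re-ordered instead.
    """
    system = influence_from_chips(group.chips)
    X_hat = fj_equilibrium(group.X0, system).X_hat
    if noise_sd == 0:
        return group.X0.replace_values(X_hat)
    if rng is None:
        rng = np.random.default_rng(seed)
    noisy = X_hat + rng.normal(0.0, noise_sd, size=X_hat.shape)
    if group.X0.simplex_constrained:
        noisy = np.clip(noisy, 0.0, None)
        sums = noisy.sum(axis=1, keepdims=True)
        # a fully clipped row (pathological at huge noise) falls back to X_hat
        bad = (sums <= 0).ravel()
        noisy[bad] = X_hat[bad]
        sums[bad] = X_hat[bad].sum(axis=1, keepdims=True)
        noisy = noisy / sums * group.supply
    else:
        half = group.m // 2
        noisy = np.clip(noisy, 0.0, group.supply)
        lo = np.minimum(noisy[:, :half], noisy[:, half:])
        hi = np.maximum(noisy[:, :half], noisy[:, half:])
        noisy = np.hstack([lo, hi])
    return group.X0.replace_values(noisy)


def generate_two_part_group(config: SyntheticConfig, n: Optional[int] = None,
                            rng: Optional[np.random.Generator] = None,
                            group_id: str = "g0"):
    """The two-part task: constraint opinions, then ideals inside them.

    Each member holds an ideal allocation (Dirichlet on the supply simplex)
    and a personal min/max constraint box around it, recorded as a 6-vector
    (min_1..min_3, max_1..max_3) with min_j <= ideal_j <= max_j by
    construction.  Returns ``(constraints_task, ideal_task)`` group records;
    chip reports are shared across the two tasks when
    ``config.share_chips`` (the same conversation produced both decisions)
    or drawn independently otherwise.
    """
    if config.m != 3:
        raise ValueError("the two-part task is defined for m = 3")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n is None:
        n = int(rng.choice(config.member_sizes))
    ideals = _draw_simplex_rows(n, config, rng)
    spread = rng.uniform(5.0, 25.0, size=(n, config.m))
    mins = np.clip(ideals - spread, 0.0, None)
    maxes = np.clip(ideals + spread, None, config.supply)
    constraints = np.hstack([mins, maxes])
    chips = _draw_chips(n, config.self_weight_law, rng)
    chips_ideal = chips if config.share_chips else _draw_chips(
        n, config.self_weight_law, rng)
    constraints_task = GroupRecord(
        group_id=f"{group_id}_constraints",
        X0=OpinionArray(constraints, supply=config.supply,
                        simplex_constrained=False),
        chips=chips, experiment_kind="two_part")
    ideal_task = GroupRecord(
        group_id=f"{group_id}_ideal",
        X0=OpinionArray(ideals, supply=config.supply),
        chips=chips_ideal, experiment_kind="two_part")
    return constraints_task, ideal_task


def generate_cohort(config: SyntheticConfig, observe: bool = True) -> list:
    """A reproducible cohort of groups with independent per-group RNG streams.

    Group sizes are drawn from ``config.member_sizes`` (default {3, 4},
    mirroring 3-4-member laboratory groups).  When ``observe`` is true each
    group also carries simulated observed finals at ``config.noise_sd``.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_groups + 1)
    size_rng = np.random.default_rng(children[0])
    sizes = size_rng.choice(config.member_sizes, size=config.n_groups)
    cohort = []
    for g in range(config.n_groups):
        rng = np.random.default_rng(children[g + 1])
        group = generate_group(config, n=int(sizes[g]), rng=rng,
                               group_id=f"g{g:03d}")
        if observe:
            group = replace(group, observed_final=simulate_observed_finals(
                group, config.noise_sd, rng=rng))
        cohort.append(group)
    return cohort
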