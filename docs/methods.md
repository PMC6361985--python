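# Methods

## Model and assumptions

The package models small-group allocation decisions as anchored weighted
averaging (Friedkin-Johnsen).  Member i's opinion row updates as a convex
combination of (a) the W-weighted average of all displayed opinions and (b)
the member's own initial opinion, with mixing weight a_ii = 1 − w_ii.  The
assumptions this encodes:

- Influence weights are fixed over the discussion (time-invariant W) and are
  measured, not estimated: each row of W is a member's 100-chip self-report
  normalized by its own total.  There are no free parameters anywhere in the
  prediction path — given X(0) and W, the prediction X̂ = V X(0) is
  deterministic.
- Multidimensional opinions update column-by-column with the same W; the
  matrix update and the per-column updates are algebraically identical (the
  implementation works with full matrices; a test checks the per-column
  equivalence).
- Because V is row-stochastic, settled opinions lie in the convex hull of
  the initial opinion rows.  The hull is contained in the coordinate-wise
  min-max polytope, which is why the model predicts settled allocations
  inside the group's implicit decision space.  Both containments are
  enforced as tested invariants rather than assumed.

Opinions for allocation issues live on the simplex slice {x ≥ 0, Σx = s};
constraint-task opinions (per-member min/max bounds, 2m values) are carried
in the same container with the simplex validation switched off.

## Parameters that matter

| parameter | units | default | rationale |
|---|---|---|---|
| iteration `tol` | opinion units | 1e-10 | one-step sup-norm change; contraction can be slow when some a_ii ≈ 1 |
| iteration `max_iter` | steps | 100,000 | paired with `tol`; non-convergence is reported, not raised |
| rcond threshold | — | 1e-12 | below this, I − AW is treated as singular and the solver falls back to iteration (pure averaging on a periodic graph is the canonical singular case) |
| row-sum validation | — | 1e-9 | W rows and simplex rows failing it are rejected, never silently repaired (chips are the one exception: they are renormalized by their own total because the construct is a relative distribution) |
| membership `tol` | allocation units | 1e-6 | subjects record integer percentages, so this is strict but safe; exposed because no canonical tolerance exists for "located on" a decision space |
| consensus `delta` | allocation units | 1e-6 | members who agree record identical numbers; raise it for noisy synthetic observations |
| vertex dedup / tie tol | units / relative | 1e-8 / 1e-9 | pin patterns coincide at corners; degenerate objectives make all vertices optimal |

## Geometry and LP

Every decision space that occurs is a box intersected with the supply
hyperplane, so the H-representation is kept as (lower, upper, supply) rather
than a general half-space list.  Vertices are enumerated exactly: pin m − 1
coordinates at a lower or upper bound, solve the free coordinate from the
supply equality, keep feasible solutions, deduplicate.  This is intended for
m ≤ 6 (the tasks use m = 3, 4, and 6-dimensional constraint vectors).  The
allocation LP is solved by scoring all vertices — for a bounded polytope an
optimum is attained at a vertex — which also yields every alternative
optimum within the tie tolerance.  Hull membership solves a small LP over
the barycentric weights, minimizing the max-norm reconstruction deviation
and accepting at deviation ≤ tol.

Lower bounds are clipped at 0 on construction (allocations are
non-negative).  Intersections may be empty; emptiness is decidable in closed
form (some l_j > u_j, or Σl > s, or Σu < s) and empty polytopes refuse
vertex enumeration.

## Evaluation

Observed and predicted opinion matrices are column-vectorized and pooled
across groups; the criterion is the product-moment correlation with a
two-sided t-test p-value (via scipy).  Change correlations always compare
observed finals minus recorded initials against X̂ − X(0) — never trajectory
increments.  Degenerate cases (e.g. a cohort in which nobody moved) yield a
flagged undefined correlation instead of NaN.  The in-space fraction tests
each member's observed final against the group's implicit polytope,
intersected with an explicit experiment-wide box when one exists; all
members are counted identically whether or not their group reached
consensus.  The Fisher exact test is computed by direct hypergeometric
enumeration over all tables with the observed margins (ties included up to
a 1e-7 relative slack), which is exact for the group-sized counts involved.

## Synthetic-data generator

The generator emulates the laboratory structure, not any particular subject
pool:

- initial opinions: symmetric Dirichlet (concentration 4.0 per dimension)
  scaled to the supply — heterogeneous but non-extreme preferences, roughly
  ±13 points per coordinate at m = 3.  With an explicit box
  (given-constraints tasks) rows are rejection-resampled into it.
- chips: self-chips uniform on {30, …, 80} (most people retain a dominant
  self-weight), the remainder split across others by a symmetric Dirichlet
  and rounded by largest remainder so each row sums to exactly 100.
- observed finals: the model equilibrium plus i.i.d. Gaussian noise
  (default sd 2.0 allocation units, the scale of integer-recorded answers),
  then clipped at 0 and rescaled to the supply.  Clip-and-rescale was chosen
  over Euclidean simplex projection for simplicity and positivity; at sd = 0
  the equilibrium is returned bit-exactly.
- the two-part task (m = 3): each member gets an ideal allocation and a
  personal min/max box around it (half-width uniform on [5, 25] points,
  clipped to [0, 100]), recorded as a 6-vector (min₁..min₃, max₁..max₃);
  ideals satisfy their own boxes by construction.  Chip reports are shared
  between the two parts by default.
- cohorts: group sizes uniform on {3, 4}; each group consumes an independent
  `SeedSequence` child, so cohorts are byte-reproducible and groups are
  uncoupled.

What the generator does *not* emulate: discussion dynamics over time
(turn-taking, talk time), subject arithmetic errors beyond chip
renormalization, correlation between a member's opinion extremity and their
self-weight, and any systematic deviation from the weighted-averaging
mechanism.  Noise is attached to observations only, never to W.  Passing
tests therefore demonstrate that the pipeline recovers the model when the
model is true and measurement is noisy — they cannot certify the mechanism
on real groups.

## Numerical choices

- Closed form via `numpy.linalg.solve` on I − AW; reciprocal condition
  below 1e-12 triggers the iterative fallback, and the singularity error
  propagates only if iteration also fails to converge.
- The DeGroot path (A = I) bypasses the closed form entirely and iterates.
- The consensus certificate implements only the sufficient aperiodicity
  condition w_ii > 0 for all i; any other configuration is labelled
  undetermined (aperiodic = None) and consensus is not certified, even when
  a globally reachable node exists.
- Fisher tie handling uses the same 1 + 1e-7 relative slack as standard
  implementations so float-level pmf ties behave deterministically.
- Problem sizes in the test suite and acceptance script (1,000 randomized
  systems with n ≤ 6, 1,000 noiseless groups, 200-group recovery cohorts,
  200 random polytopes, Fisher tables with margins ≤ 12) were chosen to
  exercise the full pipeline at the scale of the laboratory cohorts while
  keeping a complete run in seconds.

## Known limitations

- Vertex enumeration is exponential in m and intended for m ≤ 6.
- `hull_contains` targets group-sized point sets (≤ 8 points).
- The near-singular regime (some a_ii extremely close to 1 with an almost
  periodic graph) can require many iterations; the defaults accommodate it
  but convergence is then slow by nature.
- The CLI's `evaluate` recomputes predictions rather than consuming the
  `predict` output, keeping the two commands independently usable; for large
  cohorts this duplicates equilibrium solves (cheap at n ≤ 4).
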