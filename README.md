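# allocdyn

Opinion dynamics and implicit decision-space geometry for small groups
deciding how to allocate a fixed resource.

## The problem

Committees, crews and panels routinely have to agree on a *distribution*: what
percentage of a budget, of faculty positions, of daily calories goes to each
of m options, with the percentages summing to a fixed supply s.  Each member
enters the discussion with a private initial preference — a point on the
simplex slice {x ≥ 0, Σx_j = s} — and the group's array of initial preferences
automatically cuts an implicit polytope of "reasonable" compromises: the set
of allocations lying between the group's coordinate-wise minimum and maximum
initial positions,

    P = { x : l_j ≤ x_j ≤ u_j,  Σ_j x_j = s },   l_j = min_i x_ij(0),  u_j = max_i x_ij(0).

`allocdyn` implements the machinery to analyze such decisions: the
Friedkin-Johnsen (FJ) model of opinion formation under interpersonal
influence, the polytope geometry of implicit and explicit decision spaces, a
vertex-enumeration solver for the linear-programming variant of the task, an
observed-versus-predicted evaluation pipeline, and a synthetic-cohort
generator that emulates the laboratory task structure (3–4-member groups,
100-chip influence self-reports, percent-valued allocation opinions).

## The model

Opinions evolve by anchored weighted averaging.  With X(k) the n × m array of
member opinions at discussion round k, W a row-stochastic matrix of influence
weights (w_ij = weight member i places on member j's displayed opinion,
measured from 100-chip self-reports), and A = diag(a_ii), a_ii = 1 − w_ii:

    X(k+1) = A W X(k) + (I − A) X(0)

When every a_ii < 1 the settled opinions have the closed form

    X̂ = V X(0),    V = (I − A W)⁻¹ (I − A)

with V row-stochastic, so each member's settled opinion is a convex
combination of the group's initial opinions — weighted averaging can never
produce a position outside the convex hull of the initial array, and hence
never outside the implicit min-max polytope.  The DeGroot model (pure
averaging, X(k+1) = W X(k)) is the A = I special case; a certificate checks
its consensus conditions (a globally reachable node plus the w_ii > 0
aperiodicity condition).

## Worked example

A 3-member group splits a budget across three categories.  Initial opinions
(percent) and post-discussion chip reports go straight into the model:

```python
from allocdyn import FriedkinJohnsenModel

X0 = [[55.0, 25.0, 20.0],
      [45.0, 30.0, 25.0],
      [60.0, 15.0, 25.0]]
chips = [[60, 25, 15],     # member 0 kept 60 chips on self
         [20, 70, 10],
         [40, 10, 50]]
res = FriedkinJohnsenModel.from_chips(X0, chips).fit()
print(res.summary())
print("in implicit decision space:", res.in_decision_space().tolist())
```

prints

```
Friedkin-Johnsen influence model
================================================
members: 3    dimensions: 3    supply: 100
solution method: closed_form
consensus (delta=1e-6): False

member   a_ii   initial -> settled
     0  0.400   [  55.000,   25.000,   20.000] -> [  54.033,   25.048,   20.919]
     1  0.300   [  45.000,   30.000,   25.000] -> [  46.160,   29.192,   24.648]
     2  0.500   [  60.000,   15.000,   25.000] -> [  57.486,   18.626,   23.888]

total influence V (rows: members; v_ij = influence of j on i):
   0.8163  0.1257  0.0580
   0.0704  0.8992  0.0304
   0.2224  0.0935  0.6842

in implicit decision space: [True, True, True]
```

Each a_ii is the member's susceptibility (1 − self-chips/100): member 1 kept
70 chips and moves least.  The settled opinions stay between the group's
extremal initial values on every dimension — the convex-hull guarantee in
action.  Rows of V sum to 1 and give the total (direct plus indirect)
influence of each member's initial opinion on each settled opinion.

The same pipeline is scriptable from the shell:

```
allocdyn simulate --seed 1 --groups 23 --out cohort.json
allocdyn predict cohort.json --out predictions.json
allocdyn evaluate cohort.json --out summary.json
allocdyn polytope cohort.json --out spaces.json
allocdyn lp problem.json        # e.g. {"c": [1.25, 1.5, 1.75], "lower": [0.45, 0.1, 0.2], "upper": [0.65, 0.35, 0.35], "supply": 1}
```

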