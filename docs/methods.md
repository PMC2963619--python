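# Methods

## Model and procedure

The package operates on the standard constraint-based description of a
metabolic network at steady state: fluxes `v` satisfy `S v = 0` with
bounds `v_l <= v <= v_u`, and a linear objective `w` (typically biomass)
defines the FBA optimum `Z0`. Flux variability analysis then minimizes and
maximizes each flux over the region restricted by the *objective cut*
`w'v >= γ·Z0` (for a minimization objective the cut direction flips to
`w'v <= γ·Z0`). γ is accepted on the closed interval [0, 1]: γ = 1 probes
the optimal face, γ < 1 suboptimal states, and γ = 0 adds the literal row
`w'v >= 0`. That literal row is kept rather than dropped because the two
differ whenever negative objective values are feasible; callers who want
the unrestricted region use `include_objective_cut=False`. A negative `Z0`
combined with γ < 1 makes the cut *tighter* than the optimum; the engine
warns loudly and proceeds literally rather than silently reinterpreting
the request.

The sweep itself: solve FBA once (presolve permitted), append the
objective-cut row, then chain all 2n subproblems through warm starts. The
optimal FBA basis is carried into the (m+1)-row problem by making the new
row's logical column basic — the augmented basis matrix is block
triangular over the old one, so it is nonsingular, and the logical's value
`w'v0 = Z0` lies inside the cut range, so primal feasibility is preserved
without a fresh phase I. The default order runs every maximization in
reaction order and then every minimization, the minimization chain
starting from the last maximization optimum; `order="index"` interleaves
max/min per reaction instead. Because every subproblem is solved to
optimality, ranges are invariant (to 1e-6) under sweep order, chunking and
warm/cold mode; only pivot counts change. `chunks=k` splits the reaction
list into k balanced contiguous blocks, each its own warm-start chain
seeded from the initial basis — the single-process analogue of
distributing reaction subsets across CPUs.

Unbounded subproblems are reported as ±infinity with status `unbounded`,
never raised: genome-scale models routinely contain unbounded exchange or
loop fluxes. An infeasible subproblem, by contrast, aborts the run citing
γ and Z0, since all 2n problems share one region — if one is infeasible,
all are.

## The simplex engine

The builtin engine is a bounded-variable revised simplex over the equality
system `[A | -I] (x, s)' = 0`, each row carrying a logical variable with
the row's range as its bounds, so every basis has a well-defined slack
complement. Cold starts use the all-slack basis with nonbasic variables at
the bound nearer zero; phase I minimizes the sum of bound violations of
the basic variables with the composite (±1) costing, re-derived each
iteration; phase II is standard Dantzig pricing. The warm-start contract
is a `BasisState`: the ordered basic column set plus the bound status of
every nonbasic column. A warm basis is refactorized on arrival; if
singular, the engine falls back to a cold start with a warning (never a
hard failure), and if primally infeasible — possible only when the
constraints changed — it re-enters phase I from that basis, trading speed
for correctness.

Numerical choices, all conventional LP practice (feasibility and
reduced-cost tolerances 1e-9, objective comparisons at 1e-6 relative):
dense LU factorization of the basis with product-form (eta) updates and
refactorization every 50 pivots, on every warm start, and once more at
optimality for a clean solution; ratio-test ties broken by lowest column
index for determinism; degenerate-pivot runs of 1000 switch pricing to
Bland's rule, which guarantees termination on the degenerate stress
fixtures. Maximization is handled by internal negation; reported
objectives are always in the user's sense. The dense-LU design targets
toy-to-medium models (the test surface); genome-scale work should route
through the GLPK adapter, which maps `BasisState` onto GLPK's row/column
statuses one-to-one and honours the same presolve-only-on-first-solve
rule. A presolve request mid-sequence is a contract error: presolve may
rewrite the constraint system, which would invalidate every chained basis.

## Spectra

The flux spectrum is FVA at γ = 0 with optional measured fluxes imposed by
clamping `v_l = v_u` at the measured value (validated against the original
bounds). The α-spectrum builds the LP over pathway weights α >= 0 with
constraint matrix P (extreme pathways as columns) and runs the identical
sweep over the p weight columns (1 + 2p solves). Two readings are exposed
and neither is silently substituted: the literal substitution of S by P
gives `P·α = 0`, which for a pointed flux cone admits only α = 0 and is
kept for fidelity; the default reconstruction mode constrains
`P·α = v_target`, with NaN entries of `v_target` leaving the corresponding
reaction row unconstrained — this is the formulation under which pathway
weight ranges are informative.

## Synthetic data

The fixture generators define the test conditions. `make_random_model`
plants a random flux witness `v*` (entries bounded away from zero) in the
null space of a random sparse stoichiometry by correcting one coefficient
per row, then draws bounds with 0.5–5 units of slack around `v*`, makes a
random subset of positive-witness reactions irreversible, and places
sparse nonnegative objective weight on positive-witness reactions so the
FBA optimum is positive and biomass-like — hence the objective cut
`γ·Z0 <= Z0` can never empty the region. Feasibility holds by
construction, and all-finite bounds make every subproblem bounded. The
warm/cold equivalence and pivot-accounting suites use 50 such models with
m from 3 to 80 and n from 6 to 200 (mostly small, eight medium, two at
n = 150 and 200), sizes chosen so the full warm+cold comparison runs in a
couple of minutes on one CPU. What these fixtures do *not* emulate:
biological degree distributions, compartments, blocked-reaction structure,
or the numerical scaling pathologies of curated genome-scale
reconstructions — passing them demonstrates the warm-start mechanism and
LP correctness, not reader-to-result fidelity on published models, which
is checked separately against SBML fixtures and (when the files are
supplied) published genome-scale model dimensions.

`make_random_lp` generates small ranged-row LPs around a feasibility
witness for the independent oracle: exhaustive basic-solution enumeration
over `[A | -I]`, valid because with finite bounds every vertex of the
polytope is a basic solution and a bounded LP attains its optimum at one.
The oracle is capped at 4 rows x 6 columns (the enumeration is
exponential) and is the arbiter whenever it and the engine disagree.
Unboundedness, which the oracle cannot see, is tested with hand-built
cycle models instead.

## Design choices and limitations

* The JSON dialect, not any binary format, is the interchange path; SBML
  L3+FBC is the primary reader with an L2 kinetic-law/notes fallback.
  Default bounds when a file omits them: [-1000, 1000] reversible,
  [0, 1000] irreversible.
* ID uniqueness is enforced strictly with no auto-renaming — silent
  renames corrupt downstream joins.
* Extreme flux vectors are collected only behind `collect_vectors` (memory
  on large models); ranges are always reported.
* `lp_solve_count` is exactly `1 + 2·n_analyzed` in both warm and cold
  modes; pivot totals are the hardware-independent efficiency metric, and
  wall-clock comparisons are deliberately out of scope.
* The builtin engine's dense LU makes it O(m²)–O(m³) per refactorization;
  it is not intended for m in the thousands. The GLPK backend covers that
  range.
* Interior-point methods are out of scope by design: they do not
  warm-start from a basis, which is the property the whole sweep exploits.
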