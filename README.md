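# fvakit

Flux variability analysis (FVA) for constraint-based metabolic models,
built around a warm-startable bounded-variable simplex engine.

## The problem

Flux balance analysis (FBA) finds one optimal flux distribution of a
metabolic network by solving the linear program

```
max  w'v    subject to    S v = 0,    v_l <= v <= v_u
```

where `S` is the m x n stoichiometric matrix (m metabolites, n reactions),
`v` the flux vector (mmol·gDW⁻¹·h⁻¹), and `w` a biological objective such
as biomass production. The optimum `Z0 = w'v0` is unique but the flux
vector usually is not. FVA characterizes that flexibility: for every
reaction i it computes

```
max/min  v_i   subject to   S v = 0,   w'v >= γ·Z0,   v_l <= v <= v_u
```

— the attainable flux range while maintaining at least a fraction
γ ∈ [0, 1] of the optimal objective. A full analysis is 2n LPs plus the
initial FBA solve. Solving each from scratch is wasteful: all 2n problems
share one feasible region and differ only in the objective, so a
simplex-type solver can *warm-start* each solve from the previous optimal
basis, skipping phase I entirely and typically finishing in a handful of
pivots. That warm-start sweep — all maximizations chained in reaction
order, then all minimizations chained from the last maximization optimum,
with presolve disabled after the initial solve — is what this package
implements, for anyone doing network flexibility, robustness or
alternate-optima analysis on genome-scale reconstructions.

Two sibling analyses reuse the same sweep: the **flux spectrum** (γ = 0,
optionally with measured fluxes fixed) and the **α-spectrum**, which
replaces `S` by a matrix `P` of extreme pathways and ranges the
nonnegative pathway weights α in `P·α = v_target`.

## Worked example

```python
import numpy as np
from fvakit import FVAConfig, run_fva, run_fva_cold
from fvakit.fixtures import make_diamond

model = make_diamond(cap=10.0)       # uptake R1 -> A, branches R2/R3: A -> B, drain R4
result = run_fva(model, FVAConfig(gamma=1.0))
for rid, lo, hi in zip(result.reaction_ids, result.min_flux, result.max_flux):
    print(f"{rid}: [{lo:.1f}, {hi:.1f}]")
print("Z0 =", result.Z0, "| LP solves =", result.lp_solve_count)
```

prints

```
R1: [10.0, 10.0]
R2: [0.0, 10.0]
R3: [0.0, 10.0]
R4: [10.0, 10.0]
Z0 = 10.0 | LP solves = 9
```

Even on the optimal face (γ = 1) the two parallel branches each span the
whole [0, 10] range — the classic signature of alternate optima: uptake
and drain are pinned at 10, but how flux splits across R2/R3 is free.
`lp_solve_count` is exactly 1 + 2n = 9. Running `run_fva_cold` (every LP
from scratch) returns identical ranges; on larger models it needs an
order of magnitude more simplex pivots, which is the entire point of the
warm-start sweep.

The same analysis from a shell, for an SBML or JSON model:

```
fvakit fva --model model.xml --gamma 0.9 --out ranges.tsv --manifest run.json
```

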