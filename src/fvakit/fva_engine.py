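"""Flux balance analysis and warm-started flux variability analysis.

FBA solves

    max  w' v   s.t.  S v = 0,  v_l <= v <= v_u            (the FBA LP)

for the optimal objective Z0 and flux vector v0.  FVA then asks, for each
reaction i, for the minimum and maximum of v_i over the same region
restricted to (sub)optimal states:

    max/min  v_i   s.t.  S v = 0,  w'v >= gamma * Z0,  v_l <= v <= v_u

with gamma in [0, 1] selecting between the full feasible region (gamma=0)
and the optimal face (gamma=1).  A full analysis is 2n LPs plus the initial
FBA solve.

The speed trick implemented here: all 2n subproblems share one feasible
region and differ only in the objective, so each solve can warm-start from
the previous optimal basis instead of running phase I from scratch.  The
default sweep order chains all maximizations in reaction order, then all
minimizations starting from the last maximization's optimum.  Presolve, if
a backend offers one, is only permitted on the initial solve — afterwards
the constraint system must stay untouched for bases to remain valid.
Results are independent of sweep order, chunking, and warm/cold mode (each
subproblem is solved to optimality either way); only the pivot counts
differ, which is the entire point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .lp_core import (
    BASIC,
    BasisState,
    LPProblem,
    LPSolution,
    SolveOptions,
    get_backend,
)
from .model_io import MetabolicModel

__all__ = [
    "FVAConfig",
    "FVAResult",
    "FVAError",
    "InfeasibleModelError",
    "InfeasibleRegionError",
    "model_to_lp",
    "solve_fba",
    "add_objective_constraint",
    "run_fva",
    "run_fva_cold",
    "chunk_reactions",
    "classify_reactions",
]


class FVAError(RuntimeError):
    pass


class InfeasibleModelError(FVAError):
    """The FBA LP itself has no feasible flux distribution."""


class InfeasibleRegionError(FVAError):
    """The gamma-restricted region (w'v >= gamma*Z0) is infeasible."""


@dataclass
class FVAConfig:
    """Options for a variability analysis run.

    ``gamma`` is the fraction of the optimal objective that must be
    maintained (0.9 reproduces the common "at least 90% of optimality"
    setting).  ``order`` selects the warm-start chaining: ``"maxmin"`` runs
    all maximizations then all minimizations (the minimization chain starts
    from the last maximization optimum); ``"index"`` solves max then min per
    reaction.  ``chunks`` partitions the reaction list into independent
    warm-start chains, emulating distribution of reaction subsets across
    CPUs; values must be partition-invariant.
    """

    gamma: float = 0.9
    reaction_subset: Optional[Sequence[str]] = None
    backend: str = "builtin"
    order: str = "maxmin"
    chunks: int = 1
    include_objective_cut: bool = True
    collect_vectors: bool = False
    options: Optional[SolveOptions] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.order not in ("maxmin", "index"):
            raise ValueError(f"order must be 'maxmin' or 'index', got {self.order!r}")
        if self.chunks < 1:
            raise ValueError("chunks must be >= 1")


@dataclass
class FVAResult:
    model_id: str
    reaction_ids: list[str]
    Z0: float
    gamma: float
    min_flux: np.ndarray
    max_flux: np.ndarray
    status_min: list[str]
    status_max: list[str]
    lp_solve_count: int
    total_pivots: int
    warm: bool
    min_vectors: Optional[np.ndarray] = None  # (n_analyzed, n) rows, if collected
    max_vectors: Optional[np.ndarray] = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "reaction_id": self.reaction_ids,
            "minimum": self.min_flux,
            "maximum": self.max_flux,
            "status_min": self.status_min,
            "status_max": self.status_max,
        })


# ---------------------------------------------------------------------
# LP construction
# ---------------------------------------------------------------------

def model_to_lp(model: MetabolicModel) -> LPProblem:
    """The FBA LP: steady-state rows S v = 0, flux bounds, objective w."""
    m = model.n_metabolites
    zeros = np.zeros(m)
    return LPProblem(model.S, zeros, zeros, model.lower_bounds,
                     model.upper_bounds, model.objective, model.objective_sense)


def add_objective_constraint(model: MetabolicModel, gamma: float,
                             Z0: float) -> LPProblem:
    """FBA LP plus the objective cut w'v >= gamma*Z0 (row count m+1).

    For a minimize-sense model the cut is w'v <= gamma*Z0.  At gamma=0 the
    literal row w'v >= 0 is added (which differs from no row at all when
    negative objective values are feasible).
    """
    if Z0 < 0 and gamma < 1:
        warnings.warn(
            f"Z0={Z0} < 0 with gamma={gamma} < 1: the cut gamma*Z0 > Z0 "
            "tightens past the optimum and may render the region infeasible; "
            "proceeding literally")
    m = model.n_metabolites
    A = sp.vstack([model.S, sp.csr_matrix(model.objective)], format="csc")
    if model.objective_sense == "maximize":
        row_lower = np.concatenate([np.zeros(m), [gamma * Z0]])
        row_upper = np.concatenate([np.zeros(m), [np.inf]])
    else:
        row_lower = np.concatenate([np.zeros(m), [-np.inf]])
        row_upper = np.concatenate([np.zeros(m), [gamma * Z0]])
    return LPProblem(A, row_lower, row_upper, model.lower_bounds,
                     model.upper_bounds, model.objective, model.objective_sense)


def _extend_basis(basis: BasisState, n_cols: int) -> BasisState:
    """Carry an optimal FBA basis over to the cut-augmented problem.

    The new row's logical column enters the basis: the augmented basis
    matrix is block triangular over the old one, hence nonsingular, and the
    logical's value w'v0 = Z0 lies inside the cut range [gamma*Z0, inf), so
    primal feasibility is preserved and no fresh phase I is needed.
    """
    statuses = np.empty(len(basis.statuses) + 1, dtype=np.int8)
    # old logicals shift up by... layout: structurals 0..q-1 unchanged, old
    # logicals q..q+m-1 unchanged, new logical appended at q+m.
    statuses[:-1] = basis.statuses
    statuses[-1] = BASIC
    basic = np.concatenate([basis.basic_indices, [len(statuses) - 1]])
    return BasisState(basic, statuses)


# ---------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------

def solve_fba(model: MetabolicModel, backend: str = "builtin",
              options: Optional[SolveOptions] = None) -> LPSolution:
    """Solve the FBA LP from scratch (presolve permitted: first solve)."""
    if not np.any(model.objective):
        raise FVAError("model objective is all zero; set one before FBA "
                       "(e.g. with_objective(reaction_id))")
    be = get_backend(backend)
    if hasattr(be, "options") and options is not None:
        be.options = options
    be.load(model_to_lp(model), presolve=True)
    return be.solve()


# ---------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------

def _unit(n: int, j: int) -> np.ndarray:
    c = np.zeros(n)
    c[j] = 1.0
    return c


def _solve_target(be, problem_ncols, j, sense, state, warm):
    """One subproblem; updates state dict with pivots/status bookkeeping."""
    be.set_objective(_unit(problem_ncols, j), sense)
    sol = be.solve()
    state["pivots"] += sol.pivot_count
    state["solves"] += 1
    if sol.status == "infeasible":
        raise InfeasibleRegionError(
            f"region with objective cut gamma={state['gamma']} * Z0={state['Z0']} "
            "is infeasible")
    if sol.status == "optimal":
        val = sol.objective_value
    elif sol.status == "unbounded":
        val = np.inf if sense == "maximize" else -np.inf
    else:
        val = np.nan
    return sol, val


def _sweep(problem: LPProblem, targets: Sequence[int], backend: str,
           init_basis: Optional[BasisState], order: str, chunks: int,
           warm: bool, gamma: float, Z0: float, options: Optional[SolveOptions],
           collect_vectors: bool):
    """Run the 2*len(targets) min/max solves and return range arrays.

    Warm mode: one backend instance per chunk, objective changed in place,
    basis chained from solve to solve.  Cold mode: every subproblem gets a
    freshly loaded backend (the direct-implementation baseline).
    """
    nt = len(targets)
    q = problem.n_cols
    mins = np.empty(nt)
    maxs = np.empty(nt)
    st_min = [""] * nt
    st_max = [""] * nt
    vec_min = np.full((nt, q), np.nan) if collect_vectors else None
    vec_max = np.full((nt, q), np.nan) if collect_vectors else None
    state = {"pivots": 0, "solves": 0, "gamma": gamma, "Z0": Z0}

    def fresh_backend():
        be = get_backend(backend)
        if hasattr(be, "options") and options is not None:
            be.options = options
        be.load(problem, presolve=False)
        return be

    for chunk in chunk_reactions(nt, chunks):
        if warm:
            be = fresh_backend()
            if init_basis is not None:
                be.set_basis(init_basis.copy())

        def run_one(pos: int, sense: str):
            nonlocal be
            if not warm:
                be = fresh_backend()
            sol, val = _solve_target(be, q, targets[pos], sense, state, warm)
            if sense == "maximize":
                maxs[pos], st_max[pos] = val, sol.status
                if collect_vectors and sol.status == "optimal":
                    vec_max[pos] = sol.primal
            else:
                mins[pos], st_min[pos] = val, sol.status
                if collect_vectors and sol.status == "optimal":
                    vec_min[pos] = sol.primal

        if order == "maxmin":
            for pos in chunk:
                run_one(pos, "maximize")
            # minimization chain starts from the last maximization optimum
            for pos in chunk:
                run_one(pos, "minimize")
        else:  # index order: max then min per reaction
            for pos in chunk:
                run_one(pos, "maximize")
                run_one(pos, "minimize")

    return mins, maxs, st_min, st_max, vec_min, vec_max, state


def _run(model: MetabolicModel, config: FVAConfig, warm: bool) -> FVAResult:
    if config.reaction_subset is not None:
        missing = [r for r in config.reaction_subset
                   if r not in set(model.reaction_ids)]
        if missing:
            raise FVAError(f"reactions not in model: {missing}")
        targets = [model.reaction_index(r) for r in config.reaction_subset]
        target_ids = list(config.reaction_subset)
    else:
        targets = list(range(model.n_reactions))
        target_ids = list(model.reaction_ids)

    fba = solve_fba(model, config.backend, config.options)
    if fba.status == "infeasible":
        raise InfeasibleModelError(f"model {model.model_id!r}: FBA LP infeasible")
    if fba.status != "optimal":
        raise FVAError(f"FBA solve ended with status {fba.status!r}; "
                       "an optimal Z0 is required for the objective cut")
    Z0 = fba.objective_value

    if config.include_objective_cut:
        problem = add_objective_constraint(model, config.gamma, Z0)
        init_basis = (_extend_basis(fba.basis, problem.n_cols)
                      if (warm and fba.basis is not None) else None)
    else:
        problem = model_to_lp(model)
        init_basis = fba.basis if warm else None

    mins, maxs, st_min, st_max, vmin, vmax, state = _sweep(
        problem, targets, config.backend, init_basis, config.order,
        config.chunks, warm, config.gamma, Z0, config.options,
        config.collect_vectors)

    return FVAResult(
        model_id=model.model_id,
        reaction_ids=target_ids,
        Z0=Z0,
        gamma=config.gamma,
        min_flux=mins,
        max_flux=maxs,
        status_min=st_min,
        status_max=st_max,
        lp_solve_count=1 + state["solves"],
        total_pivots=fba.pivot_count + state["pivots"],
        warm=warm,
        min_vectors=vmin,
        max_vectors=vmax,
    )


def run_fva(model: MetabolicModel, config: Optional[FVAConfig] = None) -> FVAResult:
    """Warm-start flux variability analysis (1 + 2n LP solves)."""
    return _run(model, config or FVAConfig(), warm=True)


def run_fva_cold(model: MetabolicModel, config: Optional[FVAConfig] = None) -> FVAResult:
    """Direct FVA baseline: every subproblem solved from scratch.

    Produces the same ranges as :func:`run_fva` (each LP is solved to
    optimality either way); serves as the in-repo oracle and as the
    reference for pivot-count accounting.
    """
    return _run(model, config or FVAConfig(), warm=False)


# ---------------------------------------------------------------------
# post-processing / partitioning
# ---------------------------------------------------------------------

def chunk_reactions(n: int, k: int) -> list[range]:
    """Partition 0..n-1 into k contiguous chunks, sizes differing by <= 1,
    larger chunks first; k > n yields n singletons."""
    if n < 1 or k < 1:
        raise ValueError("n and k must be >= 1")
    k = min(k, n)
    base, extra = divmod(n, k)
    out = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        out.append(range(start, start + size))
        start += size
    return out


def classify_reactions(result: FVAResult, tol: float = 1e-9) -> list[str]:
    """Per-reaction class: ``blocked`` (|min|,|max| <= tol), ``fixed``
    (max-min <= tol but nonzero), else ``variable``."""
    classes = []
    for mn, mx in zip(result.min_flux, result.max_flux):
        if abs(mn) <= tol and abs(mx) <= tol:
            classes.append("blocked")
        elif mx - mn <= tol:
            classes.append("fixed")
        else:
            classes.append("variable")
    return classes
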