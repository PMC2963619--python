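"""Deterministic toy models, random LPs, and a brute-force LP oracle.

Everything here is reproducible from (kind, parameters, seed) alone via
``numpy.random.default_rng`` — no stored fixtures.  The generators cover:

* ``make_linear_pathway`` — an uptake-capped chain whose FBA optimum equals
  the cap by construction; every flux range is analytic.
* ``make_diamond`` — two parallel internal branches; the canonical probe
  for alternate optima (branch ranges [0, cap] even at gamma = 1).
* ``make_random_model`` — guaranteed-feasible random stoichiometry: a
  random flux witness v* is planted in the null space of S, and bounds are
  drawn around it with slack, so the FBA LP is never infeasible.
* ``make_random_lp`` / ``make_degenerate_lp`` — small general LPs for the
  vertex-enumeration oracle and the anti-cycling stress suite.
* ``oracle_lp_vertex_enumeration`` — an independent optimum: enumerate all
  basic solutions of [A | -I] z = 0 over bound assignments of the nonbasic
  columns and take the best feasible vertex.  Exponential, hence capped at
  r <= 4 rows and q <= 6 columns with finite bounds.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Optional, Union

import numpy as np
import scipy.sparse as sp

from .lp_core import LPProblem
from .model_io import MetabolicModel

__all__ = [
    "make_linear_pathway",
    "make_diamond",
    "make_random_model",
    "make_random_lp",
    "make_degenerate_lp",
    "oracle_lp_vertex_enumeration",
]


def make_linear_pathway(length: int = 3, cap: float = 10.0) -> MetabolicModel:
    """Chain ->M1->M2->...->(out): ``length`` reactions, ``length - 1``
    internal metabolites, uptake bounded [0, cap], objective on the
    terminal reaction.  FBA optimum = cap."""
    if length < 2:
        raise ValueError("length must be >= 2")
    m = length - 1
    rows, cols, data = [], [], []
    for j in range(length):
        if j > 0:
            rows.append(j - 1)
            cols.append(j)
            data.append(-1.0)
        if j < m:
            rows.append(j)
            cols.append(j)
            data.append(1.0)
    S = sp.coo_matrix((data, (rows, cols)), shape=(m, length))
    lo = np.zeros(length)
    up = np.full(length, max(cap, 1000.0))
    up[0] = cap
    w = np.zeros(length)
    w[-1] = 1.0
    return MetabolicModel("linear_pathway", [f"M{i+1}" for i in range(m)],
                          [f"R{j+1}" for j in range(length)], S, lo, up, w)


def make_diamond(cap: float = 10.0) -> MetabolicModel:
    """Uptake R1 -> A; parallel branches R2: A -> B and R3: A -> B;
    drain R4: B -> out with the objective.  The branch split is free, so
    R2 and R3 each range over [0, cap] even on the optimal face."""
    if cap < 0:
        raise ValueError("cap must be >= 0")
    S = np.array([
        # R1  R2  R3  R4
        [1.0, -1.0, -1.0, 0.0],   # A
        [0.0, 1.0, 1.0, -1.0],    # B
    ])
    lo = np.zeros(4)
    up = np.array([cap, 1000.0, 1000.0, 1000.0])
    w = np.array([0.0, 0.0, 0.0, 1.0])
    return MetabolicModel("diamond", ["A", "B"], ["R1", "R2", "R3", "R4"],
                          sp.csc_matrix(S), lo, up, w)


def make_random_model(m: int, n: int, seed: int,
                      density: float = 0.35) -> MetabolicModel:
    """Random feasible model: S is sparse with a planted null-space witness.

    A flux vector v* with entries in [-5, 5] (bounded away from 0) is drawn
    first; a random sparse S0 is then corrected one coefficient per row so
    that S v* = 0 exactly.  Bounds are v* plus/minus random slack in
    [0.5, 5], a random subset of reactions with v* >= slack made
    irreversible, and the objective is sparse nonnegative.  Feasibility of
    the FBA LP holds by construction (v* is a witness) and all bounds are
    finite, so FBA is always optimal.
    """
    if not (n > m >= 1):
        raise ValueError("require n > m >= 1")
    rng = np.random.default_rng(seed)
    v_star = rng.uniform(0.5, 5.0, size=n) * rng.choice([-1.0, 1.0], size=n)
    if not np.any(v_star > 0):
        v_star = -v_star
    S = np.zeros((m, n))
    for i in range(m):
        k = max(2, int(round(density * n)))
        cols = rng.choice(n, size=min(k, n), replace=False)
        S[i, cols] = np.round(rng.uniform(-3, 3, size=len(cols)), 2)
    # correct one entry per row (on a column with the largest |v*|
    # among that row's support, extended if needed) so that S v* = 0
    resid = S @ v_star
    for i in range(m):
        support = np.nonzero(S[i])[0]
        j = support[np.argmax(np.abs(v_star[support]))]
        S[i, j] -= resid[i] / v_star[j]
    # no all-zero columns: give empty columns one entry, then re-correct
    for j in range(n):
        if not np.any(S[:, j]):
            i = int(rng.integers(m))
            S[i, j] = 1.0
            k = int(np.argmax(np.abs(v_star * (np.abs(S[i]) > 0))))
            S[i, k] -= (S[i] @ v_star) / v_star[k]
    lo = v_star - rng.uniform(0.5, 5.0, size=n)
    up = v_star + rng.uniform(0.5, 5.0, size=n)
    irrev = (lo > 0) | ((rng.random(n) < 0.3) & (v_star > 0.5))
    lo[irrev] = np.maximum(lo[irrev], 0.0)
    # biomass-like objective: nonnegative weights on reactions that carry
    # positive flux at the witness, so the FBA optimum Z0 is positive and
    # the objective cut gamma*Z0 <= Z0 never empties the region
    w = np.zeros(n)
    positive = np.nonzero(v_star > 0)[0]
    n_obj = min(len(positive), max(1, n // 10))
    w[rng.choice(positive, size=n_obj, replace=False)] = rng.uniform(0.5, 2.0, n_obj)
    return MetabolicModel(f"random_m{m}_n{n}_s{seed}",
                          [f"M{i+1}" for i in range(m)],
                          [f"R{j+1}" for j in range(n)],
                          sp.csc_matrix(S), lo, up, w)


def make_random_lp(r: int, q: int, seed: int) -> LPProblem:
    """Small random LP with finite bounds and a feasibility witness.

    Rows mix equalities and ranges around A z*, so the problem is feasible
    but generally not trivially so; suitable for the enumeration oracle
    when r <= 4 and q <= 6.
    """
    rng = np.random.default_rng(seed)
    A = np.round(rng.uniform(-2, 2, size=(r, q)), 2)
    z_star = rng.uniform(-3, 3, size=q)
    act = A @ z_star
    row_lo = np.empty(r)
    row_up = np.empty(r)
    for i in range(r):
        kind = rng.random()
        if kind < 0.4:  # equality
            row_lo[i] = row_up[i] = act[i]
        else:  # range containing the activity
            row_lo[i] = act[i] - rng.uniform(0, 2)
            row_up[i] = act[i] + rng.uniform(0, 2)
    col_lo = z_star - rng.uniform(0.2, 4, size=q)
    col_up = z_star + rng.uniform(0.2, 4, size=q)
    c = np.round(rng.uniform(-3, 3, size=q), 2)
    sense = "maximize" if rng.random() < 0.5 else "minimize"
    return LPProblem(sp.csc_matrix(A), row_lo, row_up, col_lo, col_up, c, sense)


def make_degenerate_lp(seed: int) -> LPProblem:
    """LP engineered to be primal degenerate: many variables pinned at
    coincident bounds and duplicated active rows, so zero-length pivots are
    common and anti-cycling safeguards get exercised."""
    rng = np.random.default_rng(seed)
    q = 6
    base = np.round(rng.uniform(-2, 2, size=(2, q)), 1)
    A = np.vstack([base, base[0] + base[1], base[0] - base[1]])
    r = A.shape[0]
    # all rows tight at z = 0
    row_lo = np.zeros(r)
    row_up = np.where(rng.random(r) < 0.5, 0.0, rng.uniform(0, 1, size=r))
    col_lo = np.zeros(q)
    col_up = np.concatenate([np.zeros(q // 2), np.full(q - q // 2, 1.0)])
    c = np.round(rng.uniform(-1, 1, size=q), 1)
    return LPProblem(sp.csc_matrix(A), row_lo, row_up, col_lo, col_up, c,
                     "maximize")


def oracle_lp_vertex_enumeration(problem: LPProblem,
                                 tol: float = 1e-9) -> tuple[str, Optional[float]]:
    """Brute-force optimum by basic-solution enumeration.

    Works on the equality form [A | -I] z = 0 with bounds on all q + r
    columns: every vertex of the polytope is a basic solution, i.e. a
    choice of r basis columns plus a lower/upper assignment of the others.
    Returns ``("optimal", best)`` or ``("infeasible", None)``.  Restricted
    to r <= 4, q <= 6 with finite bounds (otherwise a capability error).
    """
    r, q = problem.A.shape
    if r > 4 or q > 6:
        raise ValueError("oracle limited to r <= 4, q <= 6")
    lo = np.concatenate([problem.col_lower, problem.row_lower])
    up = np.concatenate([problem.col_upper, problem.row_upper])
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(up))):
        raise ValueError("oracle requires finite bounds")
    G = np.hstack([problem.A.toarray(), -np.eye(r)])
    N = q + r
    c = np.concatenate([problem.c, np.zeros(r)])
    best = None
    for basis in combinations(range(N), r):
        B = G[:, list(basis)]
        if r and abs(np.linalg.det(B)) < 1e-10:
            continue
        nonbasic = [j for j in range(N) if j not in basis]
        choices = [(lo[j],) if lo[j] == up[j] else (lo[j], up[j])
                   for j in nonbasic]
        for assign in product(*choices):
            z = np.empty(N)
            z[nonbasic] = assign
            rhs = -G[:, nonbasic] @ z[nonbasic]
            try:
                zB = np.linalg.solve(B, rhs) if r else np.empty(0)
            except np.linalg.LinAlgError:
                continue
            z[list(basis)] = zB
            scale = np.maximum(1.0, np.maximum(np.abs(lo), np.abs(up)))
            if np.any(z < lo - tol * scale) or np.any(z > up + tol * scale):
                continue
            val = float(c @ z)
            if best is None:
                best = val
            elif problem.sense == "maximize":
                best = max(best, val)
            else:
                best = min(best, val)
    if best is None:
        return "infeasible", None
    return "optimal", best
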