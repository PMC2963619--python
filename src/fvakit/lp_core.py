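"""Bounded-variable revised simplex with explicit warm-start support.

The engine solves linear programs of the form

    min / max  c' x
    s.t.       row_lower <= A x <= row_upper
               col_lower <=  x  <= col_upper

Internally every row i carries a logical (slack) variable s_i = (A x)_i with
bounds [row_lower_i, row_upper_i], so the working system is the equality
system  [A | -I] (x, s)' = 0  over q structural plus r logical columns.  A
simplex *basis* is an ordered set of r of those q+r columns; everything the
engine needs to resume from a previous optimum is the basis plus the
bound-status of each nonbasic column, captured in :class:`BasisState`.

The warm-start contract is the point of this module: when a sequence of LPs
differs only in the objective vector, the feasible region is unchanged, so
the optimal basis of one solve is a primal-feasible starting basis for the
next, and phase I can be skipped entirely.  That is what makes sweeping
thousands of objectives over one metabolic feasible region cheap.

Numerical choices: dense LU factorization of the basis with product-form
(eta) updates, refactorization every ``refactor_every`` pivots and on every
warm start; Dantzig pricing with a switch to Bland's rule after a long run
of degenerate pivots (anti-cycling); ratio-test ties broken by lowest column
index for determinism.  The builtin engine targets toy-to-medium models;
genome-scale work should route through the GLPK backend adapter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

__all__ = [
    "LPProblem",
    "BasisState",
    "LPSolution",
    "SolveOptions",
    "AT_LOWER",
    "AT_UPPER",
    "BASIC",
    "FIXED",
    "FREE",
    "solve_lp",
    "resolve_with_new_objective",
    "backend_solve",
    "available_backends",
    "get_backend",
    "LPBackend",
    "BuiltinBackend",
    "BackendError",
    "PresolveContractError",
]

# Column status codes (shared by BasisState and the engine).
BASIC = 0
AT_LOWER = 1
AT_UPPER = 2
FIXED = 3  # col_lower == col_upper
FREE = 4  # both bounds infinite, resting at 0


class BackendError(RuntimeError):
    """Requested LP backend is unavailable or misconfigured."""


class PresolveContractError(RuntimeError):
    """Presolve requested after the first solve of a warm-start sequence."""


@dataclass
class LPProblem:
    """General LP with ranged rows and variable bounds.

    ``A`` is r x q (any scipy-sparse or dense array); an equality row has
    ``row_lower == row_upper``.  ``sense`` is ``"maximize"`` or
    ``"minimize"``.
    """

    A: sp.spmatrix
    row_lower: np.ndarray
    row_upper: np.ndarray
    col_lower: np.ndarray
    col_upper: np.ndarray
    c: np.ndarray
    sense: str = "maximize"

    def __post_init__(self) -> None:
        self.A = sp.csc_matrix(self.A, dtype=float)
        r, q = self.A.shape
        self.row_lower = np.asarray(self.row_lower, dtype=float).reshape(r)
        self.row_upper = np.asarray(self.row_upper, dtype=float).reshape(r)
        self.col_lower = np.asarray(self.col_lower, dtype=float).reshape(q)
        self.col_upper = np.asarray(self.col_upper, dtype=float).reshape(q)
        self.c = np.asarray(self.c, dtype=float).reshape(q)
        if self.sense not in ("maximize", "minimize"):
            raise ValueError(f"unknown sense {self.sense!r}")
        if np.any(self.row_lower > self.row_upper + 1e-12):
            raise ValueError("row_lower > row_upper on some row")
        if np.any(self.col_lower > self.col_upper + 1e-12):
            raise ValueError("col_lower > col_upper on some column")

    @property
    def n_rows(self) -> int:
        return self.A.shape[0]

    @property
    def n_cols(self) -> int:
        return self.A.shape[1]

    def with_objective(self, c: np.ndarray, sense: Optional[str] = None) -> "LPProblem":
        """Same feasible region, new objective (no matrix copy)."""
        new = replace(self, c=np.asarray(c, dtype=float))
        if sense is not None:
            new.sense = sense
        return new


@dataclass
class BasisState:
    """Warm-start token: ordered basic columns + nonbasic bound statuses.

    ``statuses`` has one entry per column of ``[A | -I]`` (structural columns
    first, then one logical per row, indexed q..q+r-1).  ``basic_indices``
    lists the r basic columns in basis-row order.
    """

    basic_indices: np.ndarray
    statuses: np.ndarray

    def __post_init__(self) -> None:
        self.basic_indices = np.asarray(self.basic_indices, dtype=np.int64)
        self.statuses = np.asarray(self.statuses, dtype=np.int8)
        if len(set(self.basic_indices.tolist())) != len(self.basic_indices):
            raise ValueError("duplicate basic indices")
        if not np.all(self.statuses[self.basic_indices] == BASIC):
            raise ValueError("basic_indices inconsistent with statuses")
        if int((self.statuses == BASIC).sum()) != len(self.basic_indices):
            raise ValueError("number of BASIC statuses != number of basic indices")

    def copy(self) -> "BasisState":
        return BasisState(self.basic_indices.copy(), self.statuses.copy())


@dataclass
class LPSolution:
    status: str  # optimal | infeasible | unbounded | iteration_limit
    objective_value: float
    primal: np.ndarray
    basis: Optional[BasisState]
    pivot_count: int
    used_warm_start: bool


@dataclass
class SolveOptions:
    feas_tol: float = 1e-9
    opt_tol: float = 1e-9
    pivot_tol: float = 1e-10
    max_iters: int = 0  # 0 -> auto: max(5000, 100*(r+q))
    refactor_every: int = 50
    bland_after: int = 1000  # consecutive degenerate pivots before Bland's rule


class _SingularBasis(Exception):
    pass


class _Engine:
    """One solve on the equality system G z = 0, G = [A | -I], minimizing."""

    def __init__(self, problem: LPProblem, options: SolveOptions):
        self.opts = options
        r, q = problem.A.shape
        self.r, self.q = r, q
        self.N = q + r
        G = sp.hstack([problem.A, -sp.identity(r, format="csc")], format="csc")
        self.G = G
        self.GT = G.T.tocsr()
        self.lo = np.concatenate([problem.col_lower, problem.row_lower])
        self.up = np.concatenate([problem.col_upper, problem.row_upper])
        sign = -1.0 if problem.sense == "maximize" else 1.0
        self.c = np.concatenate([sign * problem.c, np.zeros(r)])
        self.sense_sign = sign
        self.max_iters = options.max_iters or max(5000, 100 * self.N)
        self.pivots = 0
        self.degen_run = 0
        self.bland = False
        # factorization state
        self._lu = None
        self._etas: list[tuple[int, np.ndarray]] = []

    # ---------------- basis / factorization ----------------

    def set_basis(self, basis: np.ndarray, statuses: np.ndarray) -> None:
        self.basis = np.asarray(basis, dtype=np.int64).copy()
        self.status = np.asarray(statuses, dtype=np.int8).copy()
        self.refactorize()

    def default_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """All-slack basis; nonbasic structurals rest at the bound nearer zero."""
        status = np.empty(self.N, dtype=np.int8)
        for j in range(self.q):
            lo, up = self.lo[j], self.up[j]
            if lo == up:
                status[j] = FIXED
            elif np.isinf(lo) and np.isinf(up):
                status[j] = FREE
            elif np.isinf(lo):
                status[j] = AT_UPPER
            elif np.isinf(up):
                status[j] = AT_LOWER
            else:
                status[j] = AT_LOWER if abs(lo) <= abs(up) else AT_UPPER
        basis = np.arange(self.q, self.N, dtype=np.int64)
        status[basis] = BASIC
        return basis, status

    def refactorize(self) -> None:
        B = self.G[:, self.basis].toarray()
        with warnings.catch_warnings():
            # singularity is detected below via the U diagonal
            warnings.simplefilter("ignore", sla.LinAlgWarning)
            lu, piv = sla.lu_factor(B, check_finite=False)
        d = np.abs(np.diag(lu))
        if self.r and (d.min() <= 1e-12 * max(1.0, d.max())):
            raise _SingularBasis
        self._lu = (lu, piv)
        self._etas = []

    def ftran(self, v: np.ndarray) -> np.ndarray:
        x = sla.lu_solve(self._lu, v, check_finite=False)
        for p, w in self._etas:
            xp = x[p] / w[p]
            x -= xp * w
            x[p] = xp
        return x

    def btran(self, v: np.ndarray) -> np.ndarray:
        y = v.copy()
        for p, w in reversed(self._etas):
            yp = y[p] - (w @ y - w[p] * y[p])
            y[p] = yp / w[p]
        return sla.lu_solve(self._lu, y, trans=1, check_finite=False)

    # ---------------- primal values ----------------

    def nonbasic_values(self) -> np.ndarray:
        x = np.zeros(self.N)
        st = self.status
        x[st == AT_LOWER] = self.lo[st == AT_LOWER]
        x[st == AT_UPPER] = self.up[st == AT_UPPER]
        x[st == FIXED] = self.lo[st == FIXED]
        # FREE rests at 0
        return x

    def compute_xB(self, x_nb: np.ndarray) -> np.ndarray:
        rhs = -np.asarray(self.G @ x_nb).ravel()
        return self.ftran(rhs)

    # ---------------- pricing helpers ----------------

    def _entering(self, d: np.ndarray, tol: float) -> int:
        """Return entering column index, or -1 if dual-feasible."""
        st = self.status
        viol = np.zeros(self.N)
        m_lo = st == AT_LOWER
        m_up = st == AT_UPPER
        m_fr = st == FREE
        viol[m_lo] = np.maximum(-d[m_lo], 0.0)
        viol[m_up] = np.maximum(d[m_up], 0.0)
        viol[m_fr] = np.abs(d[m_fr])
        if self.bland:
            cand = np.nonzero(viol > tol)[0]
            return int(cand[0]) if cand.size else -1
        j = int(np.argmax(viol))
        return j if viol[j] > tol else -1

    def _ratio_test(self, j: int, sigma: float, w: np.ndarray, xB: np.ndarray,
                    phase1: bool, below: np.ndarray, above: np.ndarray):
        """Find blocking step.  Returns (t, leave_pos, leave_at_upper, bound_flip).

        ``below``/``above`` flag basic variables currently violating their
        lower/upper bound (phase I only; empty masks in phase II).
        """
        ptol = self.opts.pivot_tol
        delta = -sigma * w  # d(xB)/dt
        t_best = np.inf
        leave_pos = -1
        leave_up = False
        lo_B = self.lo[self.basis]
        up_B = self.up[self.basis]
        for i in range(self.r):
            di = delta[i]
            if di > ptol:
                # basic variable increasing
                if phase1 and below[i]:
                    tgt = lo_B[i]  # reaches its violated lower bound
                    at_up = False
                elif np.isfinite(up_B[i]) and not (phase1 and above[i]):
                    tgt = up_B[i]
                    at_up = True
                else:
                    continue
                t = (tgt - xB[i]) / di
            elif di < -ptol:
                if phase1 and above[i]:
                    tgt = up_B[i]
                    at_up = True
                elif np.isfinite(lo_B[i]) and not (phase1 and below[i]):
                    tgt = lo_B[i]
                    at_up = False
                else:
                    continue
                t = (tgt - xB[i]) / di
            else:
                continue
            if t < 0.0:
                t = 0.0
            if t < t_best - 1e-12:
                t_best, leave_pos, leave_up = t, i, at_up
            elif t <= t_best + 1e-12 and leave_pos >= 0:
                # deterministic tie-break: lowest column index leaves
                if self.basis[i] < self.basis[leave_pos]:
                    leave_pos, leave_up = i, at_up
        # entering variable's own opposite bound
        span = self.up[j] - self.lo[j]
        bound_flip = False
        if np.isfinite(span) and span < t_best - 1e-12:
            t_best = span
            bound_flip = True
        return t_best, leave_pos, leave_up, bound_flip

    def _count_degeneracy(self, t: float) -> None:
        if t <= 1e-12:
            self.degen_run += 1
            if self.degen_run >= self.opts.bland_after:
                self.bland = True
        else:
            self.degen_run = 0
            self.bland = False

    def _pivot(self, j: int, sigma: float, w: np.ndarray, xB: np.ndarray,
               t: float, leave_pos: int, leave_up: bool, bound_flip: bool) -> None:
        self.pivots += 1
        self._count_degeneracy(t)
        if bound_flip:
            st = self.status[j]
            if st == AT_LOWER:
                self.status[j] = AT_UPPER
            elif st == AT_UPPER:
                self.status[j] = AT_LOWER
            else:  # FREE var travelled its (finite) span — cannot happen
                raise AssertionError("bound flip on free variable")
            return
        leaving = self.basis[leave_pos]
        lo_l, up_l = self.lo[leaving], self.up[leaving]
        if lo_l == up_l:
            self.status[leaving] = FIXED
        else:
            self.status[leaving] = AT_UPPER if leave_up else AT_LOWER
        self.basis[leave_pos] = j
        self.status[j] = BASIC
        self._etas.append((leave_pos, w.copy()))
        if len(self._etas) >= self.opts.refactor_every:
            self.refactorize()

    # ---------------- phases ----------------

    def phase1(self) -> str:
        """Drive basic infeasibilities to zero.  Returns 'feasible'/'infeasible'/'iteration_limit'."""
        ftol = self.opts.feas_tol
        while True:
            if self.pivots >= self.max_iters:
                return "iteration_limit"
            x_nb = self.nonbasic_values()
            xB = self.compute_xB(x_nb)
            lo_B = self.lo[self.basis]
            up_B = self.up[self.basis]
            scale = np.maximum(1.0, np.maximum(np.abs(lo_B), np.abs(up_B)))
            scale[~np.isfinite(scale)] = 1.0
            below = xB < lo_B - ftol * scale
            above = xB > up_B + ftol * scale
            if not below.any() and not above.any():
                return "feasible"
            cB = np.where(below, -1.0, np.where(above, 1.0, 0.0))
            y = self.btran(cB)
            d = -np.asarray(self.GT @ y).ravel()
            d[self.basis] = 0.0
            j = self._entering(d, self.opts.opt_tol)
            if j < 0:
                return "infeasible"
            sigma = 1.0 if d[j] < 0 else -1.0
            w = self.ftran(self.G[:, [j]].toarray().ravel())
            t, leave_pos, leave_up, bound_flip = self._ratio_test(
                j, sigma, w, xB, True, below, above)
            if not np.isfinite(t):
                # infeasibility strictly decreasing without a breakpoint is
                # impossible (it is bounded below by 0); numerical guard.
                return "infeasible"
            self._pivot(j, sigma, w, xB, t, leave_pos, leave_up, bound_flip)

    def phase2(self) -> str:
        dtol = self.opts.opt_tol * max(1.0, np.abs(self.c).max() if self.N else 1.0)
        no_mask = np.zeros(self.r, dtype=bool)
        while True:
            if self.pivots >= self.max_iters:
                return "iteration_limit"
            x_nb = self.nonbasic_values()
            xB = self.compute_xB(x_nb)
            y = self.btran(self.c[self.basis])
            d = self.c - np.asarray(self.GT @ y).ravel()
            d[self.basis] = 0.0
            j = self._entering(d, dtol)
            if j < 0:
                return "optimal"
            sigma = 1.0 if d[j] < 0 else -1.0
            w = self.ftran(self.G[:, [j]].toarray().ravel())
            t, leave_pos, leave_up, bound_flip = self._ratio_test(
                j, sigma, w, xB, False, no_mask, no_mask)
            if not np.isfinite(t):
                return "unbounded"
            self._pivot(j, sigma, w, xB, t, leave_pos, leave_up, bound_flip)

    # ---------------- extraction ----------------

    def solution_vector(self) -> np.ndarray:
        x = self.nonbasic_values()
        xB = self.compute_xB(x)
        x[self.basis] = xB
        return x

    def result(self, status: str, used_warm: bool) -> LPSolution:
        if status == "optimal":
            try:
                self.refactorize()  # clean final factorization for accuracy
            except _SingularBasis:
                pass
        z = np.nan
        basis_state = BasisState(self.basis.copy(), self.status.copy())
        x = self.solution_vector()
        primal = x[: self.q]
        if status == "optimal":
            z = float(self.sense_sign * (self.c[: self.q] @ primal))
        elif status == "unbounded":
            z = np.inf if self.sense_sign < 0 else -np.inf
        return LPSolution(
            status=status,
            objective_value=z,
            primal=primal,
            basis=basis_state,
            pivot_count=self.pivots,
            used_warm_start=used_warm,
        )


def _run(problem: LPProblem, warm_start: Optional[BasisState],
         options: SolveOptions, skip_phase1_check: bool = False) -> LPSolution:
    eng = _Engine(problem, options)
    used_warm = False
    if warm_start is not None:
        if len(warm_start.statuses) != eng.N or len(warm_start.basic_indices) != eng.r:
            warnings.warn("warm-start basis has wrong dimensions; cold start used",
                          stacklevel=3)
        else:
            try:
                eng.set_basis(warm_start.basic_indices, warm_start.statuses)
                used_warm = True
            except _SingularBasis:
                warnings.warn("singular warm-start basis; cold start used",
                              stacklevel=3)
    if not used_warm:
        basis, status = eng.default_basis()
        eng.set_basis(basis, status)
    st = eng.phase1()
    if st == "feasible":
        st = eng.phase2()
    elif st == "infeasible":
        return eng.result("infeasible", used_warm)
    if st == "iteration_limit":
        return eng.result("iteration_limit", used_warm)
    return eng.result(st, used_warm)


def solve_lp(problem: LPProblem, warm_start: Optional[BasisState] = None,
             options: Optional[SolveOptions] = None) -> LPSolution:
    """Solve an :class:`LPProblem`, optionally warm-starting from a basis.

    Cold start: phase I from the all-slack basis (nonbasic variables at the
    bound nearer zero), then phase II.  Warm start: the given basis is
    factorized and reused; if it is primally infeasible the solve falls back
    to phase I from that basis (correctness over speed).  A singular
    warm-start basis triggers an automatic cold restart with a warning,
    never a hard failure.
    """
    return _run(problem, warm_start, options or SolveOptions())


def resolve_with_new_objective(problem: LPProblem, new_c: np.ndarray,
                               prior: LPSolution,
                               options: Optional[SolveOptions] = None,
                               sense: Optional[str] = None) -> LPSolution:
    """Re-solve after an objective-only change, reusing ``prior``'s basis.

    Because the feasible region is unchanged, the prior optimal basis is
    primal feasible by construction and phase I terminates immediately; the
    solve is pure phase II from a vertex that is typically near-optimal for
    the new objective.
    """
    new_c = np.asarray(new_c, dtype=float)
    if new_c.shape != (problem.n_cols,):
        raise ValueError(
            f"objective length {new_c.size} != number of columns {problem.n_cols}")
    if prior.status != "optimal" or prior.basis is None:
        raise ValueError("prior solution must be optimal with an attached basis")
    newp = problem.with_objective(new_c, sense)
    return _run(newp, prior.basis, options or SolveOptions())


# =====================================================================
# Backend adapters
# =====================================================================


class LPBackend:
    """Adapter contract for LP engines used in warm-start sweeps.

    Lifecycle: ``load(problem, presolve=...)`` once, then any number of
    ``set_objective`` / ``set_basis`` / ``solve`` calls.  Presolve is only
    permitted on the first solve of a sequence: afterwards the engine must
    operate on the unmodified constraint system so bases remain valid.
    """

    name = "abstract"
    supports_basis = True

    def load(self, problem: LPProblem, presolve: bool = False) -> None:
        raise NotImplementedError

    def set_objective(self, c: np.ndarray, sense: Optional[str] = None) -> None:
        raise NotImplementedError

    def set_basis(self, basis: BasisState) -> None:
        raise NotImplementedError

    def solve(self) -> LPSolution:
        raise NotImplementedError


class BuiltinBackend(LPBackend):
    name = "builtin"

    def __init__(self, options: Optional[SolveOptions] = None):
        self.options = options or SolveOptions()
        self._problem: Optional[LPProblem] = None
        self._basis: Optional[BasisState] = None
        self._solved_once = False

    def load(self, problem: LPProblem, presolve: bool = False) -> None:
        # the builtin engine has no presolver; the flag is accepted for
        # contract parity and validated the same way
        self._problem = problem
        self._basis = None
        self._solved_once = False
        self._presolve = presolve

    def set_objective(self, c: np.ndarray, sense: Optional[str] = None) -> None:
        assert self._problem is not None
        self._problem = self._problem.with_objective(c, sense)

    def set_basis(self, basis: BasisState) -> None:
        self._basis = basis

    def request_presolve(self) -> None:
        if self._solved_once:
            raise PresolveContractError(
                "presolve may only be enabled on the first solve of a sequence")
        self._presolve = True

    def solve(self) -> LPSolution:
        assert self._problem is not None, "load() a problem first"
        sol = solve_lp(self._problem, self._basis, self.options)
        self._solved_once = True
        if sol.basis is not None:
            self._basis = sol.basis
        return sol


def _make_glpk_backend():
    from .glpk_backend import GlpkBackend  # lazy: swiglpk import cost

    return GlpkBackend()


_BACKENDS = {
    "builtin": BuiltinBackend,
    "glpk": _make_glpk_backend,
}


def available_backends() -> list[str]:
    names = ["builtin"]
    try:
        import swiglpk  # noqa: F401

        names.append("glpk")
    except ImportError:
        pass
    return names


def get_backend(name: str) -> LPBackend:
    if name not in _BACKENDS:
        raise BackendError(
            f"unknown backend {name!r}; available: {available_backends()}")
    try:
        return _BACKENDS[name]()
    except ImportError as exc:
        raise BackendError(
            f"backend {name!r} unavailable ({exc}); available: {available_backends()}"
        ) from exc


def backend_solve(problem: LPProblem, warm_start: Optional[BasisState] = None,
                  backend_name: str = "builtin", presolve: bool = False,
                  options: Optional[SolveOptions] = None) -> LPSolution:
    """One-shot solve through a named backend adapter."""
    backend = get_backend(backend_name)
    if isinstance(backend, BuiltinBackend) and options is not None:
        backend.options = options
    backend.load(problem, presolve=presolve)
    if warm_start is not None:
        backend.set_basis(warm_start)
    return backend.solve()
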