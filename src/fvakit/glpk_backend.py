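"""GLPK adapter implementing the warm-start backend contract via swiglpk.

GLPK's simplex keeps an auxiliary (logical) variable per row whose bounds
are the row range — exactly the convention of the builtin engine — so basis
statuses map one-to-one.  Presolve is toggled through ``glp_smcp.presolve``
and, per the sequence contract, is only honoured on the first solve: after
that the constraint system must stay untouched so bases remain valid.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import scipy.sparse as sp
import swiglpk as glp

from .lp_core import (
    AT_LOWER,
    AT_UPPER,
    BASIC,
    FIXED,
    FREE,
    BasisState,
    LPBackend,
    LPProblem,
    LPSolution,
    PresolveContractError,
)

_TO_GLPK_STATUS = {
    BASIC: glp.GLP_BS,
    AT_LOWER: glp.GLP_NL,
    AT_UPPER: glp.GLP_NU,
    FIXED: glp.GLP_NS,
    FREE: glp.GLP_NF,
}
_FROM_GLPK_STATUS = {
    glp.GLP_BS: BASIC,
    glp.GLP_NL: AT_LOWER,
    glp.GLP_NU: AT_UPPER,
    glp.GLP_NS: FIXED,
    glp.GLP_NF: FREE,
}


def _bound_type(lo: float, up: float) -> int:
    if lo == up:
        return glp.GLP_FX
    lo_f, up_f = np.isfinite(lo), np.isfinite(up)
    if lo_f and up_f:
        return glp.GLP_DB
    if lo_f:
        return glp.GLP_LO
    if up_f:
        return glp.GLP_UP
    return glp.GLP_FR


class GlpkBackend(LPBackend):
    name = "glpk"
    supports_basis = True

    def __init__(self) -> None:
        self._prob = None
        self._q = 0
        self._r = 0
        self._presolve = False
        self._solved_once = False
        self._basis_set = False
        self._sense = "maximize"

    def __del__(self) -> None:  # pragma: no cover
        if self._prob is not None:
            glp.glp_delete_prob(self._prob)

    def load(self, problem: LPProblem, presolve: bool = False) -> None:
        if self._prob is not None:
            glp.glp_delete_prob(self._prob)
        p = glp.glp_create_prob()
        r, q = problem.A.shape
        self._prob, self._q, self._r = p, q, r
        self._presolve = presolve
        self._solved_once = False
        self._basis_set = False
        glp.glp_add_rows(p, r) if r else None
        glp.glp_add_cols(p, q) if q else None
        for i in range(r):
            lo, up = problem.row_lower[i], problem.row_upper[i]
            glp.glp_set_row_bnds(p, i + 1, _bound_type(lo, up),
                                 lo if np.isfinite(lo) else 0.0,
                                 up if np.isfinite(up) else 0.0)
        for j in range(q):
            lo, up = problem.col_lower[j], problem.col_upper[j]
            glp.glp_set_col_bnds(p, j + 1, _bound_type(lo, up),
                                 lo if np.isfinite(lo) else 0.0,
                                 up if np.isfinite(up) else 0.0)
        coo = sp.coo_matrix(problem.A)
        nnz = coo.nnz
        ia = glp.intArray(nnz + 1)
        ja = glp.intArray(nnz + 1)
        ar = glp.doubleArray(nnz + 1)
        for k, (i, j, v) in enumerate(zip(coo.row, coo.col, coo.data), start=1):
            ia[k] = int(i) + 1
            ja[k] = int(j) + 1
            ar[k] = float(v)
        glp.glp_load_matrix(p, nnz, ia, ja, ar)
        self.set_objective(problem.c, problem.sense)

    def set_objective(self, c: np.ndarray, sense: Optional[str] = None) -> None:
        if sense is not None:
            self._sense = sense
        glp.glp_set_obj_dir(
            self._prob,
            glp.GLP_MAX if self._sense == "maximize" else glp.GLP_MIN)
        c = np.asarray(c, dtype=float)
        for j in range(self._q):
            glp.glp_set_obj_coef(self._prob, j + 1, float(c[j]))

    def set_basis(self, basis: BasisState) -> None:
        self._basis_set = True
        st = basis.statuses
        for j in range(self._q):
            glp.glp_set_col_stat(self._prob, j + 1, _TO_GLPK_STATUS[int(st[j])])
        for i in range(self._r):
            glp.glp_set_row_stat(self._prob, i + 1,
                                 _TO_GLPK_STATUS[int(st[self._q + i])])

    def request_presolve(self) -> None:
        if self._solved_once:
            raise PresolveContractError(
                "presolve may only be enabled on the first solve of a sequence")
        self._presolve = True

    def _extract_basis(self) -> BasisState:
        q, r = self._q, self._r
        statuses = np.empty(q + r, dtype=np.int8)
        for j in range(q):
            statuses[j] = _FROM_GLPK_STATUS[glp.glp_get_col_stat(self._prob, j + 1)]
        for i in range(r):
            statuses[q + i] = _FROM_GLPK_STATUS[glp.glp_get_row_stat(self._prob, i + 1)]
        # GLPK exposes statuses, not basis-row ordering; index order is a
        # valid ordering for any consumer that refactorizes on warm start.
        basic_indices = np.nonzero(statuses == BASIC)[0]
        return BasisState(basic_indices, statuses)

    def solve(self) -> LPSolution:
        parm = glp.glp_smcp()
        glp.glp_init_smcp(parm)
        parm.msg_lev = glp.GLP_MSG_OFF
        parm.presolve = glp.GLP_ON if (self._presolve and not self._solved_once) else glp.GLP_OFF
        it_before = glp.glp_get_it_cnt(self._prob)
        warm = ((self._solved_once or self._basis_set)
                and parm.presolve == glp.GLP_OFF)
        ret = glp.glp_simplex(self._prob, parm)
        pivots = glp.glp_get_it_cnt(self._prob) - it_before
        self._solved_once = True
        if ret not in (0, glp.GLP_EBADB, glp.GLP_ESING, glp.GLP_ECOND):
            status = "iteration_limit"
        if ret in (glp.GLP_EBADB, glp.GLP_ESING, glp.GLP_ECOND):
            # invalid warm basis: rebuild a standard one and re-run cold
            glp.glp_std_basis(self._prob)
            ret = glp.glp_simplex(self._prob, parm)
            pivots = glp.glp_get_it_cnt(self._prob) - it_before
            warm = False
        gstat = glp.glp_get_status(self._prob)
        if gstat == glp.GLP_OPT:
            status = "optimal"
        elif gstat in (glp.GLP_NOFEAS, glp.GLP_INFEAS):
            status = "infeasible"
        elif gstat == glp.GLP_UNBND:
            status = "unbounded"
        else:
            status = "iteration_limit"
        primal = np.array(
            [glp.glp_get_col_prim(self._prob, j + 1) for j in range(self._q)])
        if status == "optimal":
            z = float(glp.glp_get_obj_val(self._prob))
        elif status == "unbounded":
            z = np.inf if self._sense == "maximize" else -np.inf
        else:
            z = float("nan")
        basis = self._extract_basis() if status in ("optimal", "unbounded") else None
        return LPSolution(
            status=status,
            objective_value=z,
            primal=primal,
            basis=basis,
            pivot_count=max(0, int(pivots)),
            used_warm_start=warm,
        )
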