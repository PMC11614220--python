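"""Thin LP helpers shared by compression, constraints and baselines.

Primary backend is scipy's HiGHS interface; a GLPK backend (via swiglpk)
is provided for cross-checking degenerate optima with an independent
solver implementation.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog

__all__ = ["solve_lp", "LPResult"]


class LPResult:
    def __init__(self, status: str, x: Optional[np.ndarray], objective: float):
        self.status = status
        self.x = x
        self.objective = objective


_SCIPY_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


def solve_lp(
    c: np.ndarray,
    A_eq: Optional[np.ndarray] = None,
    b_eq: Optional[np.ndarray] = None,
    A_ub: Optional[np.ndarray] = None,
    b_ub: Optional[np.ndarray] = None,
    bounds: Optional[Sequence[Tuple[float, float]]] = None,
    backend: str = "highs",
) -> LPResult:
    """Minimise ``c @ x`` subject to equalities, inequalities and box bounds."""
    if backend in ("highs", "highs-ds", "highs-ipm"):
        method = backend if backend != "highs" else "highs"
        res = linprog(
            c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
            method=method,
        )
        status = _SCIPY_STATUS.get(res.status, "error")
        return LPResult(status, res.x if res.x is not None else None, res.fun if res.fun is not None else float("nan"))
    if backend == "glpk":
        return _solve_glpk(c, A_eq, b_eq, A_ub, b_ub, bounds)
    raise ValueError(f"unknown LP backend {backend!r}")


def _solve_glpk(c, A_eq, b_eq, A_ub, b_ub, bounds) -> LPResult:
    import swiglpk as glp

    n = len(c)
    rows = []
    if A_eq is not None:
        rows += [(np.asarray(A_eq)[i], float(b_eq[i]), "eq") for i in range(len(b_eq))]
    if A_ub is not None:
        rows += [(np.asarray(A_ub)[i], float(b_ub[i]), "ub") for i in range(len(b_ub))]

    lp = glp.glp_create_prob()
    glp.glp_set_obj_dir(lp, glp.GLP_MIN)
    glp.glp_add_cols(lp, n)
    for j in range(n):
        lo, hi = bounds[j] if bounds is not None else (0.0, None)
        if lo is not None and hi is not None:
            kind = glp.GLP_FX if lo == hi else glp.GLP_DB
            glp.glp_set_col_bnds(lp, j + 1, kind, lo, hi)
        elif lo is not None:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_LO, lo, 0.0)
        elif hi is not None:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_UP, 0.0, hi)
        else:
            glp.glp_set_col_bnds(lp, j + 1, glp.GLP_FR, 0.0, 0.0)
        glp.glp_set_obj_coef(lp, j + 1, float(c[j]))
    glp.glp_add_rows(lp, len(rows))
    for i, (row, rhs, kind) in enumerate(rows):
        if kind == "eq":
            glp.glp_set_row_bnds(lp, i + 1, glp.GLP_FX, rhs, rhs)
        else:
            glp.glp_set_row_bnds(lp, i + 1, glp.GLP_UP, 0.0, rhs)
        idx = np.flatnonzero(row)
        ia = glp.intArray(len(idx) + 1)
        ar = glp.doubleArray(len(idx) + 1)
        for k, j in enumerate(idx):
            ia[k + 1] = int(j) + 1
            ar[k + 1] = float(row[j])
        glp.glp_set_mat_row(lp, i + 1, len(idx), ia, ar)

    parm = glp.glp_smcp()
    glp.glp_init_smcp(parm)
    parm.msg_lev = glp.GLP_MSG_OFF
    ret = glp.glp_simplex(lp, parm)
    st = glp.glp_get_status(lp)
    if ret != 0 or st not in (glp.GLP_OPT, glp.GLP_FEAS):
        status = "infeasible" if st == glp.GLP_NOFEAS else (
            "unbounded" if st == glp.GLP_UNBND else "error"
        )
        glp.glp_delete_prob(lp)
        return LPResult(status, None, float("nan"))
    x = np.array([glp.glp_get_col_prim(lp, j + 1) for j in range(n)])
    obj = glp.glp_get_obj_val(lp)
    glp.glp_delete_prob(lp)
    return LPResult("optimal", x, obj)
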