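"""Shared optimization back ends.

Two solvers cover every stage of the planning pipeline:

* :func:`solve_lp` — sparse LP via ``scipy.optimize.linprog`` (HiGHS). All
  exact stages (lexicographic MCO, L1 spot selection, MU restoration) are
  linear programs.
* :func:`solve_group_penalized` — minimize ``c @ x + lam * sum_g s_g ||x_g||_2``
  subject to ``A x <= b``, ``x >= 0``. The group norm is smoothed
  (``sqrt(||x_g||^2 + eps^2) - eps``) and the linear constraints enter through
  an escalating quadratic exterior penalty; the smooth problem is minimized
  with L-BFGS-B, warm-started from the unpenalized LP solution. The output
  is used for *selection* (which energy layers / beams carry weight); exact
  feasibility is always restored downstream by an LP on the selected support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import linprog, minimize

__all__ = [
    "InfeasibleProblemError",
    "SolverError",
    "RowGroups",
    "solve_lp",
    "solve_group_penalized",
]

FEAS_TOL_GY = 1e-3  # solver tolerance on hard dose constraints, Gy


class InfeasibleProblemError(RuntimeError):
    def __init__(self, message: str, violated: list[str] | None = None):
        super().__init__(message)
        self.violated = violated or []


class SolverError(RuntimeError):
    pass


@dataclass
class RowGroups:
    """Named contiguous row blocks of a stacked constraint matrix."""

    names: list[str]
    slices: list[slice]

    @classmethod
    def stack(cls, blocks: list[tuple[str, int]]) -> "RowGroups":
        names, slices, start = [], [], 0
        for name, n in blocks:
            names.append(name)
            slices.append(slice(start, start + n))
            start += n
        return cls(names, slices)

    def first_violated(self, residual: np.ndarray, tol: float) -> str | None:
        for name, sl in zip(self.names, self.slices):
            if residual[sl].size and residual[sl].max() > tol:
                return name
        return None


def _diagnose(A: sp.spmatrix, b: np.ndarray, groups: RowGroups | None, n_var: int) -> list[str]:
    """Minimal elastic relaxation: which constraint groups cannot be met."""
    if groups is None or A.shape[0] == 0:
        return []
    ng = len(groups.names)
    cols = []
    for sl in groups.slices:
        col = np.zeros(A.shape[0])
        col[sl] = -1.0
        cols.append(col)
    S = sp.csc_matrix(np.column_stack(cols))
    A_el = sp.hstack([sp.csc_matrix(A), S], format="csc")
    c = np.concatenate([np.zeros(n_var), np.ones(ng)])
    res = linprog(c, A_ub=A_el, b_ub=b, bounds=(0, None), method="highs")
    if not res.success:
        return list(groups.names)
    slack = res.x[n_var:]
    return [n for n, s in zip(groups.names, slack) if s > FEAS_TOL_GY]


def solve_lp(
    c: np.ndarray,
    A_ub: sp.spmatrix | None,
    b_ub: np.ndarray | None,
    bounds=(0, None),
    row_groups: RowGroups | None = None,
    context: str = "LP",
) -> np.ndarray:
    """Sparse LP; raises with named violated constraints on infeasibility."""
    A = sp.csc_matrix(A_ub) if A_ub is not None and A_ub.shape[0] else None
    b = np.asarray(b_ub, dtype=float) if A is not None else None
    res = linprog(c, A_ub=A, b_ub=b, bounds=bounds, method="highs")
    if res.status == 2:
        violated = _diagnose(A, b, row_groups, len(c)) if A is not None else []
        detail = f"; first violated constraint: {violated[0]}" if violated else ""
        raise InfeasibleProblemError(f"{context}: infeasible{detail}", violated)
    if not res.success:
        raise SolverError(f"{context}: solver failed with status {res.status}: {res.message}")
    return res.x


def solve_group_penalized(
    c: np.ndarray,
    A_ub: sp.spmatrix,
    b_ub: np.ndarray,
    groups: list[np.ndarray],
    group_weights: np.ndarray,
    lam: float,
    x0: np.ndarray | None = None,
    feas_tol: float = 1e-2,
    smooth_eps: float = 1e-3,
    row_groups: RowGroups | None = None,
    context: str = "group-penalized solve",
) -> np.ndarray:
    """Constrained group-lasso program (see module docstring).

    ``groups`` are index arrays into ``x`` (disjoint); entries of ``x`` not in
    any group carry no penalty (e.g. epigraph auxiliaries).
    """
    n = len(c)
    A = sp.csr_matrix(A_ub)
    b = np.asarray(b_ub, dtype=float)

    if x0 is None:
        x0 = solve_lp(c, A, b, row_groups=row_groups, context=context + " (warm start)")
    if lam == 0.0:
        return x0

    gw = np.asarray(group_weights, dtype=float)
    At = A.T.tocsr()

    def objective(x: np.ndarray, mu: float) -> tuple[float, np.ndarray]:
        f = float(c @ x)
        g = c.copy()
        for gi, idx in enumerate(groups):
            xg = x[idx]
            nrm = np.sqrt(xg @ xg + smooth_eps**2)
            f += lam * gw[gi] * (nrm - smooth_eps)
            g[idx] += lam * gw[gi] * xg / nrm
        r = A @ x - b
        viol = np.maximum(r, 0.0)
        f += 0.5 * mu * float(viol @ viol)
        g += mu * (At @ viol)
        return f, g

    x = x0.copy()
    scale = max(np.abs(b).max(initial=1.0), 1.0)
    mu = 10.0 * max(lam, 1.0) / scale
    for _ in range(8):
        res = minimize(
            objective,
            x,
            args=(mu,),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * n,
            options={"maxiter": 1500, "ftol": 1e-11, "gtol": 1e-8},
        )
        x = res.x
        viol = float(np.maximum(A @ x - b, 0.0).max(initial=0.0))
        if viol <= feas_tol:
            break
        mu *= 10.0
    return x
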