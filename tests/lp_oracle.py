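"""Brute-force vertex enumeration oracle for small LPs.

Independent of the solver path: the feasible polytope
{A_eq x = b_eq, A_ub x <= b_ub, lb <= x <= ub} is enumerated by activating
every subset of inequality/bound constraints that completes the equality
system to a full-rank square system, solving it, and keeping the feasible
solutions. Optima are read off the vertex list. Only usable for fixtures
with a handful of free dimensions.
"""
from __future__ import annotations

import itertools

import numpy as np

FEAS_TOL = 1e-8


def _inequality_rows(problem):
    """All inequalities as rows (a, rhs) meaning a.x <= rhs."""
    n = problem.n_vars
    rows = []
    for a, rhs in zip(problem.A_ub, problem.b_ub):
        rows.append((np.asarray(a, dtype=float), float(rhs)))
    for i in range(n):
        if np.isfinite(problem.ub[i]):
            e = np.zeros(n)
            e[i] = 1.0
            rows.append((e, float(problem.ub[i])))
        if np.isfinite(problem.lb[i]):
            e = np.zeros(n)
            e[i] = -1.0
            rows.append((e, -float(problem.lb[i])))
    return rows


def enumerate_vertices(problem, tol: float = FEAS_TOL) -> np.ndarray:
    """All vertices of the problem's feasible polytope (may be empty)."""
    n = problem.n_vars
    A_eq = np.asarray(problem.A_eq, dtype=float)
    b_eq = np.asarray(problem.b_eq, dtype=float)
    rank_eq = np.linalg.matrix_rank(A_eq) if A_eq.size else 0
    need = n - rank_eq
    ineqs = _inequality_rows(problem)
    vertices = []
    for combo in itertools.combinations(range(len(ineqs)), need):
        A = np.vstack([A_eq] + [ineqs[i][0] for i in combo]) if A_eq.size \
            else np.vstack([ineqs[i][0] for i in combo])
        b = np.concatenate([b_eq, [ineqs[i][1] for i in combo]]) if A_eq.size \
            else np.array([ineqs[i][1] for i in combo])
        if np.linalg.matrix_rank(A) < n:
            continue
        x, *_ = np.linalg.lstsq(A, b, rcond=None)
        if not np.allclose(A @ x, b, atol=1e-7):
            continue
        if A_eq.size and np.max(np.abs(A_eq @ x - b_eq)) > tol:
            continue
        if any(a @ x > rhs + tol for a, rhs in ineqs):
            continue
        if not any(np.allclose(x, v, atol=1e-7) for v in vertices):
            vertices.append(x)
    return np.array(vertices)


def oracle_optimum(problem, coefficients: dict[str, float], direction: str,
                   vertices: np.ndarray | None = None) -> float:
    """Optimal objective value over the enumerated vertices."""
    if vertices is None:
        vertices = enumerate_vertices(problem)
    if len(vertices) == 0:
        raise ValueError("polytope is empty (infeasible)")
    c = np.zeros(problem.n_vars)
    for name, w in coefficients.items():
        c[problem.index[name]] += w
    values = vertices @ c
    return float(values.max() if direction == "max" else values.min())
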