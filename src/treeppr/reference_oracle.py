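"""Slow, trusted reference solvers used for validation.

These optimize the same regression objective over the Sum Condition
polytope through general-purpose machinery that shares no code with the
tree dynamic-programming path:

* piecewise-linear / l1 losses: an exact epigraph LP solved by HiGHS;
* the l2 loss: an interior-point solve in frequency space followed by
  an active-set refinement that recovers the exact quadratic-program
  solution;
* count losses (binomial, beta-binomial): an interior-point solve over
  clone usages (``f = B^T u``; bounds plus one simplex row), whose
  geometry avoids the ill-conditioning of the clamped frequency box;
* tiny instances: exhaustive lattice search.

The production solvers never import this module; it exists for tests,
cross-checks and the reference column of benchmark comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import LinearConstraint, linprog, minimize

from .losses import (
    EPS,
    LossSpec,
    eval_loss_vector,
    loss_gradient,
    loss_hessian_diag,
)
from .tree_core import ClonalTree

__all__ = ["OracleResult", "OracleError", "oracle_solve", "grid_solve"]


class OracleError(RuntimeError):
    """Raised when the reference solver fails to converge."""


@dataclass(frozen=True)
class OracleResult:
    objective: float
    f: np.ndarray
    method: str


def _sc_constraint_matrix(tree: ClonalTree) -> tuple[sp.csr_matrix, np.ndarray]:
    """Rows: ``sum(children) - f_i <= 0`` for every vertex, plus
    ``f_root <= 1``."""
    rows, cols, data = [], [], []
    for i in range(tree.n):
        rows.append(i)
        cols.append(i)
        data.append(-1.0)
        for j in tree.children[i]:
            rows.append(i)
            cols.append(j)
            data.append(1.0)
    rows.append(tree.n)
    cols.append(tree.root)
    data.append(1.0)
    A = sp.csr_matrix((data, (rows, cols)), shape=(tree.n + 1, tree.n))
    b = np.zeros(tree.n + 1)
    b[tree.n] = 1.0
    return A, b


def oracle_solve(tree: ClonalTree, spec: LossSpec, maxiter: int = 500) -> OracleResult:
    """Reference optimum of the tree regression via general convex
    optimization (exact LP for piecewise-linear losses)."""
    if spec.n != tree.n:
        raise ValueError("loss spec and tree disagree on n")
    if spec.family in ("l1", "pwl"):
        return _oracle_lp(tree, spec)
    return _oracle_smooth(tree, spec, maxiter)


def _oracle_lp(tree: ClonalTree, spec: LossSpec) -> OracleResult:
    n = tree.n
    pieces = spec.as_pwl_pieces()
    A_sc, b_sc = _sc_constraint_matrix(tree)
    rows, cols, data, rhs = [], [], [], []
    r = 0
    # epigraph: t_i >= intercept_j + slope_j * f_i  for every piece j
    for i, piece in enumerate(pieces):
        slopes, intercepts = piece.lines()
        for m, c in zip(slopes, intercepts):
            rows += [r, r]
            cols += [i, n + i]
            data += [float(m), -1.0]
            rhs.append(-float(c))
            r += 1
    A_epi = sp.csr_matrix((data, (rows, cols)), shape=(r, 2 * n))
    A_ub = sp.vstack([A_epi, sp.hstack([A_sc, sp.csr_matrix((n + 1, n))])], format="csr")
    b_ub = np.concatenate([rhs, b_sc])
    c = np.concatenate([np.zeros(n), np.ones(n)])
    bounds = [(0.0, 1.0)] * n + [(None, None)] * n
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:
        raise OracleError(f"LP oracle failed: {res.message}")
    f = np.clip(res.x[:n], 0.0, 1.0)
    return OracleResult(float(eval_loss_vector(spec, f).sum()), f, "convex_program")


def _oracle_smooth(tree: ClonalTree, spec: LossSpec, maxiter: int) -> OracleResult:
    if spec.family == "l2":
        return _oracle_l2(tree, spec, maxiter)
    return _oracle_usage_space(tree, spec, maxiter)


def _oracle_l2(tree: ClonalTree, spec: LossSpec, maxiter: int) -> OracleResult:
    """Interior-point solve in frequency space followed by an exact
    active-set refinement of the quadratic program."""
    n = tree.n
    A, b = _sc_constraint_matrix(tree)
    x0 = _feasible_start(tree, np.clip(np.asarray(spec.f_tilde, dtype=float), 0.0, 1.0), 0.0, 1.0)

    res = minimize(
        lambda f: float(eval_loss_vector(spec, f).sum()),
        x0,
        jac=lambda f: loss_gradient(spec, f),
        hess=lambda f: sp.diags(loss_hessian_diag(spec, f), format="csr"),
        method="trust-constr",
        constraints=[LinearConstraint(A, -np.inf, b)],
        bounds=list(zip(np.zeros(n), np.ones(n))),
        options={"gtol": 1e-10, "xtol": 1e-14, "maxiter": maxiter},
    )
    if res.status not in (1, 2) and not res.success:
        raise OracleError(f"trust-constr oracle failed: {res.message}")
    f = np.clip(res.x, 0.0, 1.0)
    obj = float(eval_loss_vector(spec, f).sum())
    f, obj = _kkt_polish_l2(tree, spec, A, b, f, obj)
    return OracleResult(obj, f, "convex_program")


def _oracle_usage_space(tree: ClonalTree, spec: LossSpec, maxiter: int) -> OracleResult:
    """Interior-point solve over clone usages ``u >= 0, sum(u) <= 1``
    with ``f = B^T u``; feasibility of the frequencies is automatic and
    the bound geometry is far better conditioned than the clamped
    frequency box for count losses."""
    from .tree_core import build_clonal_matrix

    n = tree.n
    B = sp.csr_matrix(build_clonal_matrix(tree).astype(float))
    BT = B.T.tocsr()

    def fun(u: np.ndarray) -> float:
        return float(eval_loss_vector(spec, BT @ u).sum())

    def jac(u: np.ndarray) -> np.ndarray:
        return B @ loss_gradient(spec, BT @ u)

    def hessp(u: np.ndarray, p: np.ndarray) -> np.ndarray:
        h = loss_hessian_diag(spec, BT @ u)
        return B @ (h * (BT @ p))

    def run(u0: np.ndarray, iters: int):
        return minimize(
            fun,
            u0,
            jac=jac,
            hessp=hessp,
            method="trust-constr",
            constraints=[LinearConstraint(sp.csr_matrix(np.ones((1, n))), -np.inf, np.ones(1))],
            bounds=[(0.0, 1.0)] * n,
            options={
                "gtol": 1e-9,
                "xtol": 1e-14,
                "maxiter": iters,
                "factorization_method": "AugmentedSystem",
            },
        )

    # boundary optima (v = 0 or v = d mutations) make the gradient
    # criterion unattainable, and an unlucky start can stall the interior
    # point; retry from several interior points, and accept a
    # maxiter exit only when a continuation run confirms the objective
    # has stopped moving
    starts = [
        np.full(n, 0.5 / (n + 1)),
        np.full(n, 0.8 / (n + 1)),
        np.random.default_rng(12345).dirichlet(np.ones(n + 1))[:n] * 0.8,
    ]
    res = None
    best = None
    converged = False
    for u0 in starts:
        res = run(u0, maxiter)
        if best is None or res.fun < best.fun:
            best = res
        if res.status in (1, 2) or res.success:
            converged = True
            break
        if res.status == 0:  # maxiter: check value stability
            res2 = run(res.x, max(100, maxiter // 5))
            if abs(res2.fun - res.fun) <= 1e-7 * (1 + abs(res.fun)):
                res = res2
                converged = True
                break
    if not converged:
        # last resort: long continuation from the best iterate so far
        res = run(best.x, 3 * maxiter)
        res2 = run(res.x, max(100, maxiter // 5))
        if res.status not in (1, 2) and not (
            res.status == 0 and abs(res2.fun - res.fun) <= 1e-7 * (1 + abs(res.fun))
        ):
            raise OracleError(f"trust-constr oracle failed: {res.message}")
        res = res2 if res2.fun <= res.fun else res
    u = np.clip(res.x, 0.0, None)
    if u.sum() > 1.0:
        u /= u.sum()
    f = np.asarray(BT @ u).ravel()
    return OracleResult(float(eval_loss_vector(spec, f).sum()), f, "convex_program")


def _feasible_start(tree: ClonalTree, x0: np.ndarray, lb: float, ub: float) -> np.ndarray:
    from .tree_core import frequency_from_usage

    n = tree.n
    center = frequency_from_usage(tree, np.full(n, 0.8 / (n + 1)))
    # a convex combination with the center keeps strictly positive slack
    # in every Sum Condition row while staying near the data
    f = 0.5 * np.clip(x0, lb, ub) + 0.5 * center
    for i in tree.postorder():
        kids = tree.children[i]
        if kids:
            need = float(sum(f[j] for j in kids))
            if f[i] < need + 1e-9:
                f[i] = need + 1e-9
    if f[tree.root] > 1 - 1e-9:
        f *= (1 - 1e-9) / f[tree.root]
    return np.clip(f, lb, ub)


def _kkt_polish_l2(
    tree: ClonalTree,
    spec: LossSpec,
    A: sp.csr_matrix,
    b: np.ndarray,
    f: np.ndarray,
    obj: float,
) -> tuple[np.ndarray, float]:
    """Refine the interior-point solution with a primal active-set loop,
    recovering the exact quadratic-program optimum.

    The bounds 0 <= f <= 1 are implied by the Sum Condition rows plus
    the root row, so only those ``n + 1`` constraints are tracked.
    """
    n = tree.n
    w = np.asarray(spec.weights, dtype=float)
    ft = np.asarray(spec.f_tilde, dtype=float)
    Ad = A.toarray()
    resid = Ad @ f - b
    working = set(np.where(resid > -1e-5)[0].tolist())

    def solve_eq(rows: list[int]) -> tuple[np.ndarray, np.ndarray]:
        m = len(rows)
        kkt = np.zeros((n + m, n + m))
        kkt[:n, :n] = np.diag(2 * w)
        if m:
            Aeq = Ad[rows]
            kkt[:n, n:] = Aeq.T
            kkt[n:, :n] = Aeq
        rhs_full = np.concatenate([2 * w * ft, b[rows]])
        sol, *_ = np.linalg.lstsq(kkt, rhs_full, rcond=None)
        return sol[:n], sol[n:]

    best_f, best_obj = f, obj
    for _ in range(4 * n + 8):
        rows = sorted(working)
        f_new, lam = solve_eq(rows)
        # drop a wrong-signed multiplier (constraint is A f <= b, so
        # the multiplier must be nonnegative)
        if lam.size and lam.min(initial=0.0) < -1e-9:
            working.discard(rows[int(np.argmin(lam))])
            continue
        viol = Ad @ f_new - b
        worst = int(np.argmax(viol))
        if viol[worst] > 1e-10:
            if worst in working:  # degenerate; give up on polishing
                break
            working.add(worst)
            continue
        cand_obj = float(eval_loss_vector(spec, np.clip(f_new, 0.0, 1.0)).sum())
        if cand_obj < best_obj:
            best_f, best_obj = np.clip(f_new, 0.0, 1.0), cand_obj
        break
    return best_f, best_obj


def grid_solve(tree: ClonalTree, spec: LossSpec, resolution: int) -> OracleResult:
    """Exhaustive search over the Sum Condition-feasible lattice
    ``{0, 1/R, ..., 1}^n``; intended for n <= 4."""
    if tree.n > 4:
        raise ValueError("grid_solve supports n <= 4 only")
    if resolution < 1:
        raise ValueError("resolution must be positive")
    R = resolution
    best_f = None
    best_obj = np.inf
    for combo in itertools.product(range(R + 1), repeat=tree.n):
        f = np.array(combo, dtype=float) / R
        ok = f[tree.root] <= 1.0
        for i in range(tree.n):
            if f[i] < sum(f[j] for j in tree.children[i]) - 1e-12:
                ok = False
                break
        if not ok:
            continue
        obj = float(eval_loss_vector(spec, f).sum())
        if obj < best_obj:
            best_obj, best_f = obj, f
    assert best_f is not None  # f = 0 is always feasible
    return OracleResult(best_obj, best_f, "grid")
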