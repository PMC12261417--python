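"""Approximate solvers for arbitrary separable convex losses.

The exact dynamic-programming solvers cover quadratic and
piecewise-linear losses; everything else (binomial, beta-binomial, any
smooth convex family) is handled by reducing to those two primitives:

* :func:`solve_admm` — alternating directions method of multipliers on
  the split ``min L(f) + g(u)  s.t.  B^T u = f``, where ``g`` is the
  indicator of the clone-mixture simplex.  The f-update is ``n``
  independent 1D proximal problems; the u-update is an exact l2
  regression on the tree (the TSDDP l2 solver with perturbed targets);
  the dual update is an O(n) subtree-sum product.
* :func:`solve_pla_k` — replace each loss by the pointwise maximum of
  ``k - 1`` tangent lines (a convex piecewise-linear underestimator) and
  solve exactly.  For beta-Lipschitz losses the surrogate optimum is
  within ``n * beta / k`` of the true optimum.
* :func:`solve_ppla` — progressive refinement: repeat the tangent
  construction inside per-mutation frequency boxes that recenter on the
  current solution and shrink by a factor ``sigma`` each round, keeping
  the best true-loss iterate.

All three return a Sum Condition-feasible frequency vector (they end
with an exact projection or an exact piecewise-linear solve) and report
the TRUE loss at that point; surrogate optima appear in diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .losses import EPS, LossSpec, eval_loss_vector, pla_construct, prox
from .tree_core import ClonalTree, frequency_from_usage, usage_from_frequency
from .tsddp_solvers import SolveResult, solve_l2, solve_pwl

__all__ = [
    "ADMMState",
    "PPLAConfig",
    "solve_admm",
    "solve_pla_k",
    "solve_ppla",
    "pla_error_bound",
]


@dataclass
class ADMMState:
    """Iteration state of the ADMM solver (rescaled dual ``w = y / rho``)."""

    f: np.ndarray
    u: np.ndarray
    w: np.ndarray
    rho: float
    t: int = 0
    primal_residuals: list[float] | None = None
    dual_residuals: list[float] | None = None


@dataclass(frozen=True)
class PPLAConfig:
    """Progressive piecewise-linear approximation hyperparameters:
    ``k`` tangent segments per round, ``tau`` rounds, interval shrink
    factor ``sigma`` in (0, 1)."""

    k: int = 10
    tau: int = 3
    sigma: float = 0.25

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be at least 2")
        if self.tau < 1:
            raise ValueError("tau must be at least 1")
        if not 0 < self.sigma < 1:
            raise ValueError("sigma must lie strictly between 0 and 1")


def _initial_frequencies(spec: LossSpec) -> np.ndarray:
    if spec.family in ("l1", "l2"):
        return np.clip(np.asarray(spec.f_tilde, dtype=float), 0.0, 1.0)
    if spec.family in ("binomial", "betabinomial"):
        d = np.asarray(spec.d, dtype=float)
        v = np.asarray(spec.v, dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ft = np.where(d > 0, v / np.maximum(d, 1e-300), 0.0)
        return np.clip(ft, EPS, 1 - EPS)
    return np.full(spec.n, 0.5)


def solve_admm(
    tree: ClonalTree,
    spec: LossSpec,
    rho: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> SolveResult:
    """ADMM for the tree regression with any convex per-mutation loss.

    Stops when both residual norms fall below ``tol * sqrt(n)``.
    Non-convergence within ``max_iter`` is flagged in diagnostics, not
    raised.  The returned frequencies come from the final exact l2
    projection, so they satisfy the Sum Condition exactly.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    if spec.n != tree.n:
        raise ValueError("loss spec and tree disagree on n")
    n = tree.n
    f = _initial_frequencies(spec)
    # feasible warm start: one exact projection of the initial guess
    proj = solve_l2(tree, LossSpec.l2(f), want_dual=False)
    u = proj.u
    bu = frequency_from_usage(tree, u)
    w = np.zeros(n)
    threshold = tol * np.sqrt(n)
    primal_hist: list[float] = []
    dual_hist: list[float] = []
    converged = False
    t = 0
    for t in range(1, max_iter + 1):
        f = prox(spec, bu + w, rho)
        bu_prev = bu
        proj = solve_l2(tree, LossSpec.l2(f - w), want_dual=False)
        u = proj.u
        bu = proj.f  # = B^T u, exact subtree sums
        w = w + bu - f
        r_primal = float(np.linalg.norm(bu - f))
        r_dual = float(rho * np.linalg.norm(bu - bu_prev))
        primal_hist.append(r_primal)
        dual_hist.append(r_dual)
        if max(r_primal, r_dual) <= threshold:
            converged = True
            break
    f_out = bu
    objective = float(eval_loss_vector(spec, f_out).sum())
    u_out = usage_from_frequency(tree, f_out)
    return SolveResult(
        objective=objective,
        f=f_out,
        u=u_out,
        dual=None,
        diagnostics={
            "solver": "admm",
            "rho": rho,
            "iterations": t,
            "converged": converged,
            "primal_residual": primal_hist[-1] if primal_hist else 0.0,
            "dual_residual": dual_hist[-1] if dual_hist else 0.0,
        },
    )


def solve_pla_k(tree: ClonalTree, spec: LossSpec, k: int) -> SolveResult:
    """Solve with the ``k``-segment tangent underestimator of each loss.

    Reports the TRUE loss at the returned feasible point; the surrogate
    optimum (a lower bound on the true optimum) is in diagnostics, so
    ``surrogate_objective <= true optimum <= objective``.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    surrogate = LossSpec.pwl([pla_construct(spec, i, k) for i in range(spec.n)])
    res = solve_pwl(tree, surrogate)
    objective = float(eval_loss_vector(spec, res.f).sum())
    diag = dict(res.diagnostics)
    diag.update({"solver": "pla", "k": k, "surrogate_objective": res.objective})
    return SolveResult(objective=objective, f=res.f, u=res.u, dual=res.dual, diagnostics=diag)


def solve_ppla(
    tree: ClonalTree, spec: LossSpec, cfg: PPLAConfig = PPLAConfig()
) -> SolveResult:
    """Progressive PLA: ``tau`` rounds of tangent refinement in
    shrinking per-mutation frequency boxes; returns the best true-loss
    iterate (never worse than one plain PLA round at the same ``k``)."""
    n = spec.n
    lo = np.zeros(n)
    hi = np.ones(n)
    best: SolveResult | None = None
    history: list[float] = []
    for _ in range(cfg.tau):
        surrogate = LossSpec.pwl(
            [
                pla_construct(spec, i, cfg.k, bounds=(float(lo[i]), float(hi[i])))
                for i in range(n)
            ]
        )
        res = solve_pwl(tree, surrogate)
        true_obj = float(eval_loss_vector(spec, res.f).sum())
        history.append(true_obj)
        if best is None or true_obj < best.objective:
            best = SolveResult(
                objective=true_obj,
                f=res.f,
                u=res.u,
                dual=res.dual,
                diagnostics={"surrogate_objective": res.objective},
            )
        width = cfg.sigma * (hi - lo)
        lo = np.clip(res.f - width / 2, 0.0, 1.0)
        hi = np.clip(res.f + width / 2, 0.0, 1.0)
        # keep a nonempty interior for the tangent points
        tiny = width < 16 * EPS
        lo[tiny] = np.maximum(lo[tiny] - 8 * EPS, 0.0)
        hi[tiny] = np.minimum(hi[tiny] + 8 * EPS, 1.0)
    assert best is not None
    diag = dict(best.diagnostics)
    diag.update(
        {"solver": "ppla", "k": cfg.k, "tau": cfg.tau, "sigma": cfg.sigma, "round_objectives": history}
    )
    return SolveResult(
        objective=best.objective, f=best.f, u=best.u, dual=best.dual, diagnostics=diag
    )


def pla_error_bound(n: int, beta: float, k: int) -> float:
    """Worst-case surrogate gap ``n * beta / k`` of the ``k``-segment
    tangent approximation for beta-Lipschitz convex losses."""
    if n < 0 or beta < 0:
        raise ValueError("n and beta must be nonnegative")
    if k < 1:
        raise ValueError("k must be at least 1")
    return n * beta / k
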