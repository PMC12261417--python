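"""Exact tree-structured dual dynamic programming (TSDDP) solvers.

The regression problem — minimize a separable convex loss over the Sum
Condition polytope of a fixed clonal tree — is Lagrangian-dual to a
*tree separable* concave maximization over one multiplier per vertex
(plus one for the root bound ``f_root <= 1``).  Writing
``h_i(x) = min_f {L_i(f) - x f}`` for the concave tilted minimum of each
loss, the dual is

    max_{alpha >= 0}  -alpha_0 + sum_i h_i(alpha_i - alpha_parent(i)),

which a bottom-up dynamic program solves exactly.  Each vertex carries a
concave value function

    J_i(gamma) = max_{alpha_i >= 0} { h_i(alpha_i - gamma)
                                      + sum_{children j} J_j(alpha_i) },

and the solvers differ only in the closed representation of ``J_i``:

* weighted l2 loss: ``J_i`` is piecewise quadratic; we store the scalar
  structure of its piecewise-linear, non-increasing derivative ``J_i'``.
  The inductive step merges the children's derivatives and composes
  through the stationarity map ``gamma(alpha) = alpha
  + 2 w_i (ftilde_i - C_i'(alpha))``, which is piecewise linear and
  strictly increasing, so the composition stays piecewise linear.
* convex piecewise-linear loss (l1 included): ``J_i`` is concave
  piecewise linear; we store its non-increasing step derivative.  The
  inductive step is a sup-convolution, realized as a slope-sorted
  segment merge of the two derivatives.

After the bottom-up pass, the root solves a 1D problem and a top-down
pass recovers the dual certificate and primal frequencies.  For
piecewise-linear losses the optimal face can be degenerate, so primal
recovery uses three passes: multipliers top-down (smallest optimal
``alpha_i``), realizable frequency intervals bottom-up (intersecting
tilted-argmin intervals with complementary-slackness constraints), and a
final top-down allocation choosing the smallest realizable ``f_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .losses import LossSpec, PiecewiseLinearConvex, conjugate_h, eval_loss_vector
from .tree_core import ClonalTree, usage_from_frequency

__all__ = [
    "DualCertificate",
    "SolveResult",
    "solve_l2",
    "solve_pwl",
    "dual_objective",
]

_TOL = 1e-11


@dataclass(frozen=True)
class DualCertificate:
    """Multipliers for the root bound (``alpha0``) and the n Sum
    Condition inequalities (``alpha[i]`` for vertex ``i``)."""

    alpha0: float
    alpha: np.ndarray

    def as_vector(self) -> np.ndarray:
        return np.concatenate(([self.alpha0], self.alpha))


@dataclass(frozen=True)
class SolveResult:
    """Output of a single-sample regression solve."""

    objective: float
    f: np.ndarray
    u: np.ndarray
    dual: DualCertificate | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)


def dual_objective(tree: ClonalTree, spec: LossSpec, cert: DualCertificate) -> float:
    """Evaluate the Lagrangian dual ``-alpha0 + sum_i h_i(alpha_i -
    alpha_parent(i))``; a lower bound on the primal optimum for any
    feasible multipliers, tight at the solver's certificate."""
    alpha = np.asarray(cert.alpha, dtype=float)
    if alpha.shape != (tree.n,) or cert.alpha0 < -_TOL or np.any(alpha < -_TOL):
        raise ValueError("dual certificate must be nonnegative of length n")
    total = -cert.alpha0
    for i in range(tree.n):
        parent = tree.parent[i]
        a_par = cert.alpha0 if i == tree.root else alpha[parent]
        total += conjugate_h(spec, i, float(alpha[i] - a_par))[0]
    return float(total)


# ---------------------------------------------------------------------------
# weighted l2 loss
# ---------------------------------------------------------------------------
#
# For L_i(f) = w (f - ft)^2 the tilted minimum is closed form:
#     h(x) = -x^2 / (4 w) - x ft,     argmin f = ft + x / (2 w).
# At a vertex with child-sum derivative C'(alpha) (piecewise linear,
# non-increasing), the inner maximizer alpha*(gamma) satisfies
#     gamma = alpha + 2 w (ft - C'(alpha))        (alpha* > 0)
# and clamps to 0 for gamma <= gamma0 = 2 w (ft - C'(0)).  The envelope
# theorem gives J'(gamma) = C'(alpha*(gamma)) on the unclamped side and
# J'(gamma) = ft - gamma / (2 w) on the clamped side.


class _L2Node:
    """Per-vertex state for the l2 solver."""

    __slots__ = ("w", "ft", "xs_c", "ys_c", "sr_c", "gvals", "jxs", "jys", "jsl", "jsr")

    def __init__(self) -> None:
        self.xs_c = None  # C' breakpoints on [0, inf), first entry 0
        self.ys_c = None  # C' values there
        self.sr_c = 0.0  # C' slope beyond the last breakpoint


def _pl_eval(xs: np.ndarray, ys: np.ndarray, sl: float, sr: float, x: np.ndarray) -> np.ndarray:
    """Evaluate a continuous piecewise-linear function given breakpoint
    values and the two end slopes."""
    out = np.interp(x, xs, ys)
    out = np.where(x < xs[0], ys[0] + sl * (x - xs[0]), out)
    out = np.where(x > xs[-1], ys[-1] + sr * (x - xs[-1]), out)
    return out


def solve_l2(tree: ClonalTree, spec: LossSpec, want_dual: bool = True) -> SolveResult:
    """Exact minimizer of ``sum_i w_i (f_i - ftilde_i)^2`` over the Sum
    Condition polytope with ``f_root <= 1``.

    Strict convexity makes both the objective and the minimizer unique.
    ``want_dual=False`` skips the dual-objective evaluation in the
    diagnostics (used on the hot path of the ADMM projection).
    """
    if spec.family != "l2":
        raise ValueError("solve_l2 requires an l2 loss spec")
    if spec.n != tree.n:
        raise ValueError("loss spec and tree disagree on n")
    w = np.asarray(spec.weights, dtype=float)
    ft = np.asarray(spec.f_tilde, dtype=float)
    if np.any(w <= 0):
        raise ValueError("l2 weights must be strictly positive")

    nodes = [_L2Node() for _ in range(tree.n)]
    for i in range(tree.n):
        nodes[i].w = float(w[i])
        nodes[i].ft = float(ft[i])

    for i in tree.postorder():
        node = nodes[i]
        kids = tree.children[i]
        if not kids:
            # leaf: J'(gamma) = ft - gamma/(2w) until gamma0 = 2 w ft, 0 after
            node.jxs = np.array([2 * node.w * node.ft])
            node.jys = np.array([0.0])
            node.jsl = -1.0 / (2 * node.w)
            node.jsr = 0.0
            continue
        # child-sum derivative C' = sum_j J_j'
        if len(kids) == 1:
            k = nodes[kids[0]]
            all_x, ys_sum = k.jxs, k.jys
            sl_sum, sr_sum = k.jsl, k.jsr
        else:
            all_x = np.unique(np.concatenate([nodes[j].jxs for j in kids]))
            ys_sum = np.zeros_like(all_x)
            sl_sum = 0.0
            sr_sum = 0.0
            for j in kids:
                k = nodes[j]
                ys_sum = ys_sum + _pl_eval(k.jxs, k.jys, k.jsl, k.jsr, all_x)
                sl_sum += k.jsl
                sr_sum += k.jsr
        # restrict C' to alpha >= 0
        pos = all_x > 0.0
        if pos.all():
            c0 = float(_pl_eval(all_x, ys_sum, sl_sum, sr_sum, np.array([0.0]))[0])
            xs_c = np.concatenate(([0.0], all_x))
            ys_c = np.concatenate(([c0], ys_sum))
            sr_c = sr_sum
        elif not pos.any():
            c0 = float(ys_sum[-1] + sr_sum * (0.0 - all_x[-1]))
            xs_c = np.array([0.0])
            ys_c = np.array([c0])
            sr_c = sr_sum
        else:
            c0 = float(_pl_eval(all_x, ys_sum, sl_sum, sr_sum, np.array([0.0]))[0])
            xs_c = np.concatenate(([0.0], all_x[pos]))
            ys_c = np.concatenate(([c0], ys_sum[pos]))
            sr_c = sr_sum
        node.xs_c, node.ys_c, node.sr_c = xs_c, ys_c, sr_c
        # stationarity map gamma(alpha), strictly increasing piecewise linear
        gvals = xs_c + 2 * node.w * (node.ft - ys_c)
        node.gvals = gvals
        node.jxs = gvals
        node.jys = ys_c
        node.jsl = -1.0 / (2 * node.w)
        denom = 1.0 - 2 * node.w * sr_c
        node.jsr = sr_c / denom

    # root step: maximize -alpha0 + J_r(alpha0) over alpha0 >= 0
    r = tree.root
    root = nodes[r]
    jr0 = float(_pl_eval(root.jxs, root.jys, root.jsl, root.jsr, np.array([0.0]))[0])
    if jr0 <= 1.0 + _TOL:
        alpha0 = 0.0
    else:
        alpha0 = _pl_solve_decreasing(root.jxs, root.jys, root.jsl, root.jsr, 1.0)

    # top-down backtracking
    alpha = np.zeros(tree.n)
    f = np.zeros(tree.n)
    for i in tree.bfs_order:
        node = nodes[i]
        gamma = alpha0 if i == tree.root else alpha[tree.parent[i]]
        if not tree.children[i]:
            a = max(0.0, gamma - 2 * node.w * node.ft)
        else:
            a = _l2_alpha_star(node, gamma)
        alpha[i] = a
        f[i] = node.ft + (a - gamma) / (2 * node.w)

    np.clip(f, 0.0, 1.0, out=f)
    u = usage_from_frequency(tree, f)
    objective = float(eval_loss_vector(spec, f).sum())
    cert = DualCertificate(alpha0, np.maximum(alpha, 0.0))
    diag = {"solver": "tsddp_l2"}
    if want_dual:
        diag["dual_objective"] = dual_objective(tree, spec, cert)
    return SolveResult(objective=objective, f=f, u=u, dual=cert, diagnostics=diag)


def _pl_solve_decreasing(
    xs: np.ndarray, ys: np.ndarray, sl: float, sr: float, target: float
) -> float:
    """Smallest x with value <= target for a non-increasing PL function
    that is known to start above the target."""
    if ys[0] <= target:
        # crossing happens on the leftmost slope-sl segment
        return float(xs[0] - (ys[0] - target) / sl) if sl != 0 else float(xs[0])
    idx = int(np.searchsorted(-ys, -target, side="left"))  # first ys <= target
    if idx >= ys.size:
        if sr >= 0:
            return float(xs[-1])
        return float(xs[-1] + (target - ys[-1]) / sr)
    x0, x1 = xs[idx - 1], xs[idx]
    y0, y1 = ys[idx - 1], ys[idx]
    if y0 == y1:
        return float(x0)
    return float(x0 + (target - y0) * (x1 - x0) / (y1 - y0))


def _l2_alpha_star(node: "_L2Node", gamma: float) -> float:
    """Invert the stationarity map at an internal vertex; clamps at 0."""
    g = node.gvals
    if gamma <= g[0]:
        return 0.0
    idx = int(np.searchsorted(g, gamma, side="right")) - 1
    if idx >= g.size - 1:
        slope = 1.0 - 2 * node.w * node.sr_c
        return float(node.xs_c[-1] + (gamma - g[-1]) / slope)
    dg = g[idx + 1] - g[idx]
    dx = node.xs_c[idx + 1] - node.xs_c[idx]
    return float(node.xs_c[idx] + (gamma - g[idx]) * dx / dg)


# ---------------------------------------------------------------------------
# convex piecewise-linear loss (l1 included)
# ---------------------------------------------------------------------------
#
# With the loss domain restricted to [0, 1], the tilted minimum h(x) is
# concave piecewise linear with slopes -f* in [-1, 0]; its reflection
# hhat(z) = h(-z) is non-decreasing with slopes in [0, 1].  Every value
# function J_i then has a non-increasing step derivative with values in
# [0, 1] ending at exactly 0, and the inductive step is the
# sup-convolution of hhat with the child-sum restricted to [0, inf).


class _StepFn:
    """A non-increasing step function: value ``vs[t]`` on the open
    interval between breakpoints ``xs[t-1]`` and ``xs[t]``."""

    __slots__ = ("xs", "vs")

    def __init__(self, xs: np.ndarray, vs: np.ndarray) -> None:
        self.xs = xs
        self.vs = vs

    @staticmethod
    def normalized(xs: np.ndarray, vs: np.ndarray) -> "_StepFn":
        """Drop zero-length pieces and merge equal-valued neighbours."""
        # remove zero-length intervals (xs[t] == xs[t+1] kills vs[t+1])
        if xs.size:
            keep_x = np.ones(xs.size, dtype=bool)
            keep_x[1:] = np.diff(xs) > 1e-15
            if not keep_x.all():
                keep_v = np.concatenate(([True], keep_x))
                xs, vs = xs[keep_x], vs[keep_v]
        # merge neighbours with (numerically) equal values
        if xs.size:
            diff = -np.diff(vs)
            keep = diff > 1e-13
            xs, vs = xs[keep], np.concatenate((vs[:1], vs[1:][keep]))
        return _StepFn(xs, vs)

    def value_right(self, x: float) -> float:
        return float(self.vs[np.searchsorted(self.xs, x, side="right")])

    def value_left(self, x: float) -> float:
        return float(self.vs[np.searchsorted(self.xs, x, side="left")])


def _hhat_derivative(piece: PiecewiseLinearConvex) -> _StepFn:
    """Step derivative of ``hhat(z) = min_{f in [0,1]} {L(f) + z f}``.

    Breakpoints sit at the negated loss slopes; values are the argmin
    frequencies, running from 1 down to 0.
    """
    m = piece.slopes
    bp = np.clip(piece.breakpoints, 0.0, 1.0)
    xs = -m[::-1]
    vs = np.concatenate(([1.0], bp[::-1], [0.0]))
    return _StepFn.normalized(xs, vs)


def _step_sum(parts: list[_StepFn]) -> _StepFn:
    if len(parts) == 1:
        return parts[0]
    all_x = np.unique(np.concatenate([p.xs for p in parts]))
    vs = np.zeros(all_x.size + 1)
    for p in parts:
        idx = np.concatenate(([0], np.searchsorted(p.xs, all_x, side="right")))
        vs += p.vs[idx]
    return _StepFn.normalized(all_x, vs)


def _step_restrict(fn: _StepFn) -> _StepFn:
    """Restrict to [0, inf): drop breakpoints at or left of 0."""
    idx0 = int(np.searchsorted(fn.xs, 0.0, side="right"))
    return _StepFn(fn.xs[idx0:], fn.vs[idx0:])


def _supconv_derivative(hs: _StepFn, cs: _StepFn | None) -> _StepFn:
    """Step derivative of ``M(gamma) = max_{alpha >= 0} {hhat(gamma -
    alpha) + C(alpha)}`` from the derivatives of its two ingredients.

    The slopes of ``M`` are the union of both slope sets capped at
    ``hhat``'s top slope, and each breakpoint is the sum of the positions
    at which the two derivatives drop past the same level.
    """
    if cs is None or cs.vs.size == 1 and cs.vs[0] == 0.0:
        # no children (or flat child-sum): M' = hhat' since hhat is
        # non-decreasing on the original axis
        return hs
    shmax = float(hs.vs[0])
    levels = np.unique(np.concatenate((hs.vs, cs.vs)))[::-1]
    levels = levels[levels < shmax - 1e-13]
    slopes = np.concatenate(([shmax], levels))
    # collapse levels that are numerically identical
    keep = np.concatenate(([True], -np.diff(slopes) > 1e-13))
    slopes = slopes[keep]
    mids = 0.5 * (slopes[:-1] + slopes[1:])
    xs = np.empty(mids.size)
    for t, lam in enumerate(mids):
        cnt_h = int(np.sum(hs.vs > lam))
        xh = float(hs.xs[cnt_h - 1])  # hhat always starts above lam
        cnt_c = int(np.sum(cs.vs > lam))
        xc = 0.0 if cnt_c == 0 else float(cs.xs[cnt_c - 1])
        xs[t] = xh + xc
    return _StepFn.normalized(xs, slopes)


def solve_pwl(tree: ClonalTree, spec: LossSpec) -> SolveResult:
    """Exact minimizer for convex piecewise-linear losses over the Sum
    Condition polytope (l1 is converted to a two-piece function).

    Ties on flat optimal faces are broken deterministically: smallest
    optimal multiplier at every vertex, then the smallest frequency
    realizable on the optimal face.
    """
    if spec.family not in ("l1", "pwl"):
        raise ValueError("solve_pwl requires an l1 or pwl loss spec")
    if spec.n != tree.n:
        raise ValueError("loss spec and tree disagree on n")
    pieces = spec.as_pwl_pieces()

    hs_all: list[_StepFn] = [_hhat_derivative(p) for p in pieces]
    cs_all: list[_StepFn | None] = [None] * tree.n
    j_all: list[_StepFn] = [None] * tree.n  # type: ignore[assignment]

    for i in tree.postorder():
        kids = tree.children[i]
        if kids:
            cs = _step_restrict(_step_sum([j_all[j] for j in kids]))
            cs_all[i] = cs
        else:
            cs = None
        j_all[i] = _supconv_derivative(hs_all[i], cs)

    # every J has slopes <= 1, so -alpha0 + J_r(alpha0) is non-increasing
    # and the root-bound multiplier vanishes: f <= 1 is already enforced
    # through the loss domain
    alpha0 = 0.0

    # pass A: smallest optimal multipliers, top-down
    alpha = np.zeros(tree.n)
    for i in tree.bfs_order:
        gamma = alpha0 if i == tree.root else alpha[tree.parent[i]]
        alpha[i] = _smallest_alpha(hs_all[i], cs_all[i], gamma)

    # pass B: realizable frequency intervals on the optimal face, bottom-up
    lo = np.zeros(tree.n)
    hi = np.zeros(tree.n)
    for i in tree.postorder():
        gamma = alpha0 if i == tree.root else alpha[tree.parent[i]]
        a, b = pieces[i].argmin_interval(tilt=float(alpha[i] - gamma))
        kids = tree.children[i]
        lo_kids = float(sum(lo[j] for j in kids))
        hi_kids = float(sum(hi[j] for j in kids))
        if alpha[i] > _TOL:
            # active Sum Condition: children must sum exactly to f_i
            # (for a leaf the empty sum forces f_i = 0)
            lo[i] = max(a, lo_kids)
            hi[i] = min(b, hi_kids)
        else:
            lo[i] = max(a, lo_kids)
            hi[i] = b
        if lo[i] > hi[i]:  # numerical slack on a degenerate face
            mid = 0.5 * (lo[i] + hi[i])
            lo[i] = hi[i] = mid

    # pass C: allocate frequencies top-down, smallest realizable first
    f = np.zeros(tree.n)
    for i in tree.bfs_order:
        if i == tree.root:
            f[i] = 1.0 if alpha0 > _TOL else lo[i]
        kids = tree.children[i]
        if not kids:
            continue
        if alpha[i] > _TOL:
            target = f[i]
        else:
            target = float(sum(lo[j] for j in kids))
        surplus = target - float(sum(lo[j] for j in kids))
        for j in kids:
            extra = min(max(surplus, 0.0), hi[j] - lo[j])
            f[j] = lo[j] + extra
            surplus -= extra

    np.clip(f, 0.0, 1.0, out=f)
    u = usage_from_frequency(tree, f)
    objective = float(eval_loss_vector(spec, f).sum())
    cert = DualCertificate(alpha0, np.maximum(alpha, 0.0))
    return SolveResult(
        objective=objective,
        f=f,
        u=u,
        dual=cert,
        diagnostics={"solver": "tsddp_pwl", "dual_objective": dual_objective(tree, spec, cert)},
    )


def _smallest_alpha(hs: _StepFn, cs: _StepFn | None, gamma: float) -> float:
    """Smallest maximizer of ``hhat(gamma - alpha) + C(alpha)`` over
    ``alpha >= 0`` given the two step derivatives.

    The objective is concave piecewise linear in alpha with kinks at the
    candidate points below; the derivative is evaluated at interval
    *midpoints*, which is robust to breakpoints that nearly coincide
    after float arithmetic (evaluating exactly at a kink is not).
    """
    cands = [0.0]
    if cs is not None:
        cands.extend(float(x) for x in cs.xs)
    cands.extend(gamma - float(z) for z in hs.xs if gamma - float(z) > _TOL)
    cands = sorted(set(cands))
    for t, a in enumerate(cands):
        nxt = cands[t + 1] if t + 1 < len(cands) else a + 1.0
        mid = 0.5 * (a + nxt)
        # slope of the objective on (a, nxt)
        d = -hs.value_right(gamma - mid)
        if cs is not None:
            d += cs.value_right(mid)
        if d <= _TOL:
            return a
    return cands[-1]
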