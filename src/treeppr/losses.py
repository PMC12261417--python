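"""Separable convex loss families and their conjugates.

Each mutation ``i`` contributes a convex term ``L_i(f_i)`` to the
regression objective.  Supported families:

``l2``
    ``w_i (f_i - ftilde_i)^2`` with per-mutation weights ``w_i > 0``.
``l1``
    ``|f_i - ftilde_i|``.
``pwl``
    an arbitrary convex piecewise-linear function on ``[0, 1]``.
``binomial``
    ``-[v ln f + (d - v) ln(1 - f)]``, the negative binomial
    log-likelihood of ``v`` variant reads out of ``d`` with the
    f-independent binomial coefficient dropped.
``betabinomial``
    the negative beta-binomial log-mass under a mean-precision
    parameterization ``alpha = f s``, ``beta = (1 - f) s`` with a single
    global precision ``s``, constants dropped.

The dual building block of the tree solvers is the tilted minimum
``h_i(x) = min_f {L_i(f) - x f}``, the negated convex conjugate of
``L_i``; it is concave in ``x`` regardless of ``L_i``.  Count losses have
divergent gradients at 0 and 1, so all 1D minimizations for them run on
the clamped interval ``[EPS, 1 - EPS]``; piecewise-linear and l1 losses
are minimized over ``[0, 1]``, and the l2 loss over the whole real line.

Because additive constants are dropped, reported objectives are
comparable only within a fixed set of read counts ``(V, D)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln, psi

__all__ = [
    "EPS",
    "PiecewiseLinearConvex",
    "LossSpec",
    "eval_loss",
    "loss_gradient",
    "conjugate_h",
    "tilted_argmin",
    "prox",
    "pla_construct",
]

#: domain clamp for count losses; keeps h finite at the boundary tilts
EPS = 1e-9

_SLOPE_TOL = 1e-12


@dataclass(frozen=True)
class PiecewiseLinearConvex:
    """A convex piecewise-linear function on ``[0, 1]``.

    ``slopes`` are strictly increasing; ``breakpoints`` (strictly
    increasing, one fewer than slopes) separate the pieces; the anchor
    ``(x0, y0)`` fixes the function value at one point.
    """

    breakpoints: np.ndarray
    slopes: np.ndarray
    anchor: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        bp = np.asarray(self.breakpoints, dtype=float)
        sl = np.asarray(self.slopes, dtype=float)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "slopes", sl)
        if sl.ndim != 1 or sl.size < 1:
            raise ValueError("need at least one slope")
        if bp.size != sl.size - 1:
            raise ValueError("need exactly len(slopes) - 1 breakpoints")
        if bp.size and np.any(np.diff(bp) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(np.diff(sl) <= 0):
            raise ValueError("slopes must be strictly increasing (convexity)")
        # value at each breakpoint, derived once from the anchor
        object.__setattr__(self, "_bp_values", self._values_at_breakpoints())

    def _values_at_breakpoints(self) -> np.ndarray:
        bp, sl = self.breakpoints, self.slopes
        x0, y0 = self.anchor
        if bp.size == 0:
            return np.empty(0)
        vals = np.empty(bp.size)
        # piece containing the anchor
        j0 = int(np.searchsorted(bp, x0, side="left"))
        # walk right then left from the anchor
        v = y0
        x = x0
        for j in range(j0, bp.size):
            v = v + sl[j] * (bp[j] - x)
            vals[j] = v
            x = bp[j]
        v = y0
        x = x0
        for j in range(j0 - 1, -1, -1):
            v = v - sl[j + 1] * (x - bp[j])
            vals[j] = v
            x = bp[j]
        return vals

    def __call__(self, f: float | np.ndarray) -> float | np.ndarray:
        f = np.asarray(f, dtype=float)
        bp, sl = self.breakpoints, self.slopes
        if bp.size == 0:
            x0, y0 = self.anchor
            out = y0 + sl[0] * (f - x0)
            return float(out) if out.ndim == 0 else out
        vals: np.ndarray = self._bp_values  # type: ignore[attr-defined]
        idx = np.searchsorted(bp, f, side="left")
        ref_x = bp[np.clip(idx - 1, 0, bp.size - 1)]
        ref_v = vals[np.clip(idx - 1, 0, bp.size - 1)]
        # for f left of the first breakpoint, reference the first breakpoint
        left = idx == 0
        ref_x = np.where(left, bp[0], ref_x)
        ref_v = np.where(left, vals[0], ref_v)
        out = ref_v + sl[idx] * (f - ref_x)
        return float(out) if out.ndim == 0 else out

    def lines(self) -> tuple[np.ndarray, np.ndarray]:
        """The pieces as lines ``y = intercept + slope * f`` (the function
        is their pointwise maximum)."""
        bp, sl = self.breakpoints, self.slopes
        x0, y0 = self.anchor
        if bp.size == 0:
            return sl.copy(), np.array([y0 - sl[0] * x0])
        vals: np.ndarray = self._bp_values  # type: ignore[attr-defined]
        intercepts = np.empty(sl.size)
        intercepts[0] = vals[0] - sl[0] * bp[0]
        intercepts[1:] = vals - sl[1:] * bp
        return sl.copy(), intercepts

    def argmin_interval(self, tilt: float = 0.0) -> tuple[float, float]:
        """The interval of minimizers of ``L(f) - tilt * f`` over [0, 1]."""
        sl = self.slopes - tilt
        bp = self.breakpoints
        knots = np.concatenate(([0.0], np.clip(bp, 0.0, 1.0), [1.0]))
        if sl[0] > _SLOPE_TOL:
            return 0.0, 0.0
        if sl[-1] < -_SLOPE_TOL:
            return 1.0, 1.0
        # first piece with slope >= -tol starts the flat/increasing region
        pos = int(np.searchsorted(sl, -_SLOPE_TOL, side="left"))
        lo = knots[pos]
        # last piece with slope <= +tol ends it
        pos_hi = int(np.searchsorted(sl, _SLOPE_TOL, side="right"))
        hi = knots[pos_hi]
        lo = float(np.clip(lo, 0.0, 1.0))
        hi = float(np.clip(hi, 0.0, 1.0))
        return (lo, hi) if lo <= hi else (lo, lo)


_FAMILIES = ("l1", "l2", "pwl", "binomial", "betabinomial")


@dataclass(frozen=True)
class LossSpec:
    """Per-mutation loss parameters for one sample.

    Use the constructors :meth:`l2`, :meth:`l1`, :meth:`pwl`,
    :meth:`binomial`, :meth:`betabinomial`.
    """

    family: str
    n: int
    f_tilde: np.ndarray | None = None
    weights: np.ndarray | None = None
    v: np.ndarray | None = None
    d: np.ndarray | None = None
    s: float | None = None
    pieces: tuple[PiecewiseLinearConvex, ...] | None = None

    @staticmethod
    def l2(f_tilde: Sequence[float], weights: Sequence[float] | None = None) -> "LossSpec":
        f_tilde = np.asarray(f_tilde, dtype=float)
        w = np.ones_like(f_tilde) if weights is None else np.asarray(weights, dtype=float)
        if w.shape != f_tilde.shape:
            raise ValueError("weights and f_tilde must have the same length")
        if np.any(w <= 0):
            raise ValueError("l2 weights must be strictly positive")
        return LossSpec("l2", f_tilde.size, f_tilde=f_tilde, weights=w)

    @staticmethod
    def l1(f_tilde: Sequence[float]) -> "LossSpec":
        f_tilde = np.asarray(f_tilde, dtype=float)
        return LossSpec("l1", f_tilde.size, f_tilde=f_tilde)

    @staticmethod
    def pwl(pieces: Sequence[PiecewiseLinearConvex]) -> "LossSpec":
        pieces = tuple(pieces)
        return LossSpec("pwl", len(pieces), pieces=pieces)

    @staticmethod
    def binomial(v: Sequence[float], d: Sequence[float]) -> "LossSpec":
        v = np.asarray(v, dtype=float)
        d = np.asarray(d, dtype=float)
        _check_counts(v, d)
        return LossSpec("binomial", v.size, v=v, d=d)

    @staticmethod
    def betabinomial(
        v: Sequence[float], d: Sequence[float], s: float = 100.0
    ) -> "LossSpec":
        v = np.asarray(v, dtype=float)
        d = np.asarray(d, dtype=float)
        _check_counts(v, d)
        if s <= 0:
            raise ValueError("precision s must be positive")
        spec = LossSpec("betabinomial", v.size, v=v, d=d, s=float(s))
        _validate_betabinomial_convexity(spec)
        return spec

    def as_pwl_pieces(self) -> tuple[PiecewiseLinearConvex, ...]:
        """The piecewise-linear view used by the exact PL solver.

        l1 converts to a two-piece function with slopes -1 and +1 and its
        breakpoint at the observed frequency.
        """
        if self.family == "pwl":
            assert self.pieces is not None
            return self.pieces
        if self.family == "l1":
            assert self.f_tilde is not None
            out = []
            for ft in self.f_tilde:
                out.append(
                    PiecewiseLinearConvex(
                        np.array([float(ft)]),
                        np.array([-1.0, 1.0]),
                        anchor=(float(ft), 0.0),
                    )
                )
            return tuple(out)
        raise ValueError(f"loss family {self.family!r} is not piecewise linear")


def _check_counts(v: np.ndarray, d: np.ndarray) -> None:
    if v.shape != d.shape:
        raise ValueError("v and d must have the same length")
    if np.any(v < 0) or np.any(d < 0):
        raise ValueError("read counts must be nonnegative")
    if np.any(v > d):
        bad = int(np.argmax(v > d))
        raise ValueError(f"variant count exceeds total count at mutation {bad}")


def _validate_betabinomial_convexity(spec: LossSpec, grid: int = 64) -> None:
    # convexity of the negative beta-binomial log-likelihood in f is
    # assumed for the solvers; checked numerically here, warn on failure
    f = np.linspace(EPS, 1 - EPS, grid)
    for i in range(min(spec.n, 32)):
        vals = np.array([_eval_one(spec, i, x) for x in f])
        second = np.diff(vals, 2)
        if np.any(second < -1e-7 * (1 + np.abs(vals).max())):
            warnings.warn(
                "beta-binomial loss appears non-convex on a grid for "
                f"mutation {i}; solver optimality is not guaranteed",
                stacklevel=3,
            )
            return


# ---------------------------------------------------------------------------
# pointwise evaluation and gradients
# ---------------------------------------------------------------------------

def _clamped(f: np.ndarray) -> np.ndarray:
    return np.clip(f, EPS, 1 - EPS)


def _eval_one(spec: LossSpec, i: int, f: float) -> float:
    return float(eval_loss_vector(spec, np.full(spec.n, f))[i])


def eval_loss_vector(spec: LossSpec, f: np.ndarray) -> np.ndarray:
    """Per-mutation losses ``L_i(f_i)`` for a full frequency vector."""
    f = np.asarray(f, dtype=float)
    if f.shape != (spec.n,):
        raise ValueError(f"expected frequency vector of length {spec.n}")
    if spec.family == "l2":
        return spec.weights * (f - spec.f_tilde) ** 2
    if spec.family == "l1":
        return np.abs(f - spec.f_tilde)
    if spec.family == "pwl":
        return np.array([float(p(x)) for p, x in zip(spec.pieces, f)])
    fc = _clamped(f)
    if spec.family == "binomial":
        return -(spec.v * np.log(fc) + (spec.d - spec.v) * np.log1p(-fc))
    if spec.family == "betabinomial":
        s = spec.s
        a, b = fc * s, (1 - fc) * s
        return -(
            gammaln(spec.v + a)
            - gammaln(a)
            + gammaln(spec.d - spec.v + b)
            - gammaln(b)
        )
    raise ValueError(f"unknown loss family {spec.family!r}")


def eval_loss(spec: LossSpec, i: int, f: float) -> float:
    """Evaluate ``L_i(f)``; count losses clamp ``f`` into [EPS, 1-EPS]."""
    if not 0 <= i < spec.n:
        raise IndexError(f"mutation index {i} out of range for n={spec.n}")
    return _eval_one(spec, i, f)


def loss_gradient(spec: LossSpec, f: np.ndarray) -> np.ndarray:
    """Vector of derivatives ``L_i'(f_i)``; differentiable families only."""
    f = np.asarray(f, dtype=float)
    if spec.family == "l2":
        return 2 * spec.weights * (f - spec.f_tilde)
    fc = _clamped(f)
    if spec.family == "binomial":
        return -spec.v / fc + (spec.d - spec.v) / (1 - fc)
    if spec.family == "betabinomial":
        s = spec.s
        a, b = fc * s, (1 - fc) * s
        return -s * (psi(spec.v + a) - psi(a)) + s * (psi(spec.d - spec.v + b) - psi(b))
    raise ValueError(f"loss family {spec.family!r} is not differentiable")


def total_loss(spec: LossSpec, f: np.ndarray) -> float:
    """Sum of per-mutation losses at ``f``."""
    return float(eval_loss_vector(spec, f).sum())


def loss_hessian_diag(spec: LossSpec, f: np.ndarray) -> np.ndarray:
    """Vector of second derivatives ``L_i''(f_i)``; smooth families only."""
    f = np.asarray(f, dtype=float)
    if spec.family == "l2":
        return 2 * spec.weights * np.ones_like(f)
    fc = _clamped(f)
    if spec.family == "binomial":
        return spec.v / fc**2 + (spec.d - spec.v) / (1 - fc) ** 2
    if spec.family == "betabinomial":
        s = spec.s
        a, b = fc * s, (1 - fc) * s
        from scipy.special import polygamma

        t1 = polygamma(1, spec.v + a) - polygamma(1, a)
        t2 = polygamma(1, spec.d - spec.v + b) - polygamma(1, b)
        return -(s**2) * (t1 + t2)
    raise ValueError(f"loss family {spec.family!r} is not twice differentiable")


# ---------------------------------------------------------------------------
# tilted minimization: h(x) = min_f {L(f) - x f}
# ---------------------------------------------------------------------------

def tilted_argmin(spec: LossSpec, i: int, x: float) -> float:
    """Smallest minimizer of ``L_i(f) - x f`` over the loss domain."""
    return conjugate_h(spec, i, x)[1]


def conjugate_h(spec: LossSpec, i: int, x: float) -> tuple[float, float]:
    """``h_i(x) = min_f {L_i(f) - x f}`` and its smallest minimizer.

    ``h`` is concave in ``x`` and ``h(0)`` equals the unconstrained
    minimum of the loss.  Domains: all reals for l2, ``[0, 1]`` for
    l1/pwl, ``[EPS, 1-EPS]`` for the count losses.
    """
    if not 0 <= i < spec.n:
        raise IndexError(f"mutation index {i} out of range for n={spec.n}")
    if spec.family == "l2":
        w = float(spec.weights[i])
        ft = float(spec.f_tilde[i])
        fstar = ft + x / (2 * w)
        return -(x * x) / (4 * w) - x * ft, fstar
    if spec.family in ("l1", "pwl"):
        piece = spec.as_pwl_pieces()[i]
        lo, _ = piece.argmin_interval(tilt=x)
        return float(piece(lo)) - x * lo, lo
    fstar = _tilted_argmin_count(spec, i, x)
    val = _eval_one(spec, i, fstar) - x * fstar
    return val, fstar


def _tilted_argmin_count(spec: LossSpec, i: int, x: float) -> float:
    v = float(spec.v[i])
    d = float(spec.d[i])
    lo, hi = EPS, 1 - EPS
    if d == 0:
        # zero-information mutation: loss is identically 0; the tilt picks
        # an endpoint, smallest on ties
        return lo if x <= 0 else hi
    if spec.family == "binomial":
        # solve L'(f) = x:  x f^2 + (d - x) f - v = 0  (monotone L')
        if v == 0.0:
            f = 1 - d / x if x > d else 0.0
        elif v == d:
            f = -d / x if x < -d else 1.0
        else:
            disc = (d - x) ** 2 + 4 * x * v
            denom = (d - x) + np.sqrt(max(disc, 0.0))
            f = 2 * v / denom if denom > 0 else 1.0
        return float(np.clip(f, lo, hi))
    # beta-binomial: bisection on the monotone derivative
    def g(f: float) -> float:
        return float(loss_gradient(spec, np.full(spec.n, f))[i]) - x

    if g(lo) >= 0:
        return lo
    if g(hi) <= 0:
        return hi
    a, b = lo, hi
    for _ in range(80):
        m = 0.5 * (a + b)
        if g(m) < 0:
            a = m
        else:
            b = m
    return 0.5 * (a + b)


def prox(spec: LossSpec, a: np.ndarray, rho: float) -> np.ndarray:
    """Vectorized proximal step ``argmin_f L_i(f) + (rho/2)(f - a_i)^2``.

    The workhorse of the ADMM f-update.  Count losses are solved on
    ``[EPS, 1-EPS]`` by safeguarded bisection on the monotone gradient.
    """
    a = np.asarray(a, dtype=float)
    if rho <= 0:
        raise ValueError("rho must be positive")
    if spec.family == "l2":
        return (rho * a + 2 * spec.weights * spec.f_tilde) / (rho + 2 * spec.weights)
    if spec.family == "l1":
        ft = spec.f_tilde
        shrunk = np.where(
            a > ft + 1 / rho, a - 1 / rho, np.where(a < ft - 1 / rho, a + 1 / rho, ft)
        )
        return np.clip(shrunk, 0.0, 1.0)
    if spec.family == "pwl":
        out = np.empty(spec.n)
        for i, piece in enumerate(spec.as_pwl_pieces()):
            out[i] = _prox_pwl(piece, float(a[i]), rho)
        return out
    # count losses: bisect L'(f) + rho (f - a) on [EPS, 1-EPS]
    lo = np.full(spec.n, EPS)
    hi = np.full(spec.n, 1 - EPS)

    def g(f: np.ndarray) -> np.ndarray:
        return loss_gradient(spec, f) + rho * (f - a)

    glo, ghi = g(lo), g(hi)
    done_lo = glo >= 0
    done_hi = ghi <= 0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        neg = g(mid) < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    out = 0.5 * (lo + hi)
    out[done_lo] = EPS
    out[done_hi & ~done_lo] = 1 - EPS
    return out


def _prox_pwl(piece: PiecewiseLinearConvex, a: float, rho: float) -> float:
    knots = np.concatenate(([0.0], piece.breakpoints, [1.0]))
    best_f, best_val = 0.0, np.inf
    for j, m in enumerate(piece.slopes):
        f = float(np.clip(a - m / rho, knots[j], knots[j + 1]))
        val = float(piece(f)) + 0.5 * rho * (f - a) ** 2
        if val < best_val - 1e-15:
            best_f, best_val = f, val
    return best_f


# ---------------------------------------------------------------------------
# tangent-based piecewise-linear approximation
# ---------------------------------------------------------------------------

def pla_construct(
    spec: LossSpec,
    i: int,
    k: int,
    bounds: tuple[float, float] | None = None,
) -> PiecewiseLinearConvex:
    """Tangent underestimator of ``L_i`` with ``k - 1`` tangent lines.

    Tangents are taken at ``x_j = j/k`` for ``j = 1..k-1`` (or at evenly
    spaced points inside ``bounds``, used by the progressive scheme) and
    the result is their pointwise maximum, a convex piecewise-linear
    function that underestimates ``L_i`` everywhere and converges to it
    pointwise as ``k`` grows.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if spec.family in ("l1", "pwl"):
        raise ValueError(
            f"{spec.family} loss is not differentiable; use the pwl solver directly"
        )
    lo, hi = (0.0, 1.0) if bounds is None else bounds
    if not lo < hi:
        raise ValueError("bounds must satisfy lo < hi")
    # tangent points stay strictly inside (0, 1): count-loss gradients
    # diverge at the boundary
    xs = lo + (hi - lo) * np.arange(1, k) / k
    xs = np.clip(xs, EPS, 1 - EPS)
    ys = np.array([_eval_one(spec, i, float(x)) for x in xs])
    grads = _gradient_at(spec, i, xs)
    # drop tangents whose slope ties an earlier one (identical line for a
    # convex function)
    keep = np.concatenate(([True], np.diff(grads) > _SLOPE_TOL))
    xs, ys, grads = xs[keep], ys[keep], grads[keep]
    if xs.size == 1:
        return PiecewiseLinearConvex(
            np.empty(0), grads, anchor=(float(xs[0]), float(ys[0]))
        )
    intercepts = ys - grads * xs
    bp = (intercepts[:-1] - intercepts[1:]) / (grads[1:] - grads[:-1])
    return PiecewiseLinearConvex(bp, grads, anchor=(float(xs[0]), float(ys[0])))


def _gradient_at(spec: LossSpec, i: int, xs: np.ndarray) -> np.ndarray:
    grads = np.empty(xs.size)
    for j, x in enumerate(xs):
        grads[j] = float(loss_gradient(spec, np.full(spec.n, float(x)))[i])
    return grads
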