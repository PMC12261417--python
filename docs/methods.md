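# Methods

## The regression problem

Bulk DNA sequencing of a tumor measures, for each somatic mutation
`i`, a variant read count `v_i` out of a total depth `d_i`, so the
observed variant allele frequency `v_i / d_i` is a noisy estimate of
the latent frequency `f_i` with which the mutation occurs in the
sample.  Under the infinite sites assumption the mutations evolve down
a rooted clonal tree `T`, each vertex (clone) identified with the
mutation gained on its incoming edge, and the sample is a mixture of
clones with proportions `u >= 0`, `sum(u) <= 1` (the slack is the
normal-cell fraction).  The latent frequencies are then exactly the
subtree sums of the usages, `f = B^T u` with `B` the clonal matrix,
which holds iff `f` satisfies the Sum Condition

    f_i >= sum_{j in children(i)} f_j   for all i,    f_root <= 1.

Given the tree, the counts, and a separable convex loss
`L(f) = sum_i L_i(f_i)`, the package computes

    min { L(f) : f in SC polytope of T },

together with the usage vector, a Lagrangian dual certificate (for the
exact solvers) and diagnostics.  Multi-sample inputs separate across
samples and are solved row by row.

## Loss families

| family        | `L_i(f)`                                         | domain          |
|---------------|--------------------------------------------------|-----------------|
| `l2`          | `w_i (f - ftilde_i)^2`, `w_i > 0`                | all reals       |
| `l1`          | `abs(f - ftilde_i)`                              | `[0, 1]`        |
| `pwl`         | convex piecewise linear                          | `[0, 1]`        |
| `binomial`    | `-[v ln f + (d - v) ln(1 - f)]`                  | `[eps, 1 - eps]`|
| `betabinomial`| `-ln BetaBin(v; d, f s, (1 - f) s)` (mean-precision) | `[eps, 1 - eps]`|

Additive constants that do not depend on `f` (binomial coefficients,
beta-function terms in the totals) are dropped, so objectives are
comparable only within a fixed `(V, D)`.  The clamp `eps = 1e-9` keeps
the count losses and their tilted minima finite at the boundary; all 1D
minimizations for count losses run on `[eps, 1 - eps]`, and pointwise
evaluation clamps its argument into the same interval.  The
beta-binomial uses a single global precision `s` (default 100; larger
is closer to binomial); its convexity in `f` holds for this
mean-precision parameterization and is additionally checked numerically
on a grid when a loss specification is built, with a warning on
failure.  Mutations
with `d_i = 0` carry no information; their loss is identically zero and
they are representable as a one-piece piecewise-linear loss with slope
zero.

## Exact solvers: dual dynamic programming on the tree

Associating a multiplier `alpha_i >= 0` with each Sum Condition row and
`alpha_0 >= 0` with `f_root <= 1` gives the tree-separable Lagrangian
dual

    max_{alpha >= 0}  -alpha_0 + sum_i h_i(alpha_i - alpha_parent(i)),
    h_i(x) = min_f { L_i(f) - x f },

with strong duality for convex losses.  A bottom-up pass propagates the
concave value functions

    J_i(gamma) = max_{alpha_i >= 0} { h_i(alpha_i - gamma)
                                      + sum_{children j} J_j(alpha_i) },

the root solves `max_{alpha_0 >= 0} { -alpha_0 + J_r(alpha_0) }`, and a
top-down pass recovers the multipliers and the primal frequencies.

**Weighted l2.**  `h` is an explicit parabola, so each `J_i'` is a
continuous, non-increasing piecewise-linear function, stored as
breakpoints and values.  The inductive step sums the children's
derivatives on the merged breakpoint grid and composes through the
stationarity map `gamma(alpha) = alpha + 2 w_i (ftilde_i - C'(alpha))`,
which is piecewise linear and strictly increasing (slope at least 1, so
the inversion is numerically safe); clamping `alpha >= 0` contributes
one extra breakpoint.  Backtracking inverts the stored maps and sets
`f_i = ftilde_i + (alpha_i - alpha_parent(i)) / (2 w_i)`.  Strict
convexity makes the answer unique.

**Convex piecewise linear (l1 included).**  With the loss domain
`[0, 1]`, `h` is concave piecewise linear with slopes `-f*` in
`[-1, 0]`; every `J_i` therefore has a non-increasing *step* derivative
with values in `[0, 1]` ending at exactly 0.  The inductive step is a
sup-convolution, computed as a slope-sorted merge of the two step
derivatives: for each slope level, the position where the merged
derivative drops past that level is the sum of the positions at which
the two ingredients do.  Because the loss domain already enforces
`f <= 1`, the root multiplier `alpha_0` is always 0 for this solver;
the certificate still satisfies strong duality under this partial
dualization.

*Degenerate faces.*  Piecewise-linear problems have flat optimal faces,
and recovering a primal point from the duals requires care: selecting
each mutation's smallest tilted argmin independently can violate
complementary slackness (a two-vertex chain with l1 losses at 0.2 and
0.5 already breaks it).  Recovery therefore uses three passes: (1)
top-down, the smallest optimal multiplier at every vertex, evaluating
the concave objective's slope on candidate-interval midpoints (robust
to breakpoints that nearly coincide after float arithmetic); (2)
bottom-up, the interval of frequencies realizable on the optimal face —
the tilted-argmin interval intersected with the children's interval sum
when the vertex's multiplier is positive (complementary slackness
forces the Sum Condition tight there; for a leaf it forces `f = 0`);
(3) top-down, the smallest realizable frequency, with any surplus
distributed to children in ascending id order.  The result is
deterministic across runs and platforms.

Numerical choices: breakpoints or slopes closer than `1e-13` are
merged; multiplier positivity uses tolerance `1e-11`; tilts are matched
to loss slopes within `1e-12` when computing argmin intervals.

## Approximate solvers for count losses

**ADMM.**  The splitting `min L(f) + indicator(u in mixture simplex)`
subject to `B^T u = f` alternates (a) `n` independent proximal steps
`argmin L_i(f) + (rho/2)(f - a_i)^2`, solved by safeguarded bisection
on the monotone gradient, (b) an exact l2 tree regression with
perturbed targets (the TSDDP solver as projection subroutine), and (c)
a rescaled dual update using the O(n) subtree-sum product instead of a
materialized `B`.  Defaults: `rho = 1`, `tol = 1e-6` (residual norms
compared with `tol * sqrt(n)`), `max_iter = 1000`, warm start at the
projected observed frequencies.  Non-convergence is flagged in
diagnostics rather than raised; the returned point always comes from
the final exact projection and is feasible.  Note that the linear
convergence rate degrades as `rho / curvature`; binomial losses at
depth `d` have curvature of order `d / (f (1 - f))`, so deep-coverage
instances converge slowly at `rho = 1` and the iteration budget, not
the tolerance, may bind.

**PLA-k.**  Each differentiable loss is replaced by the pointwise
maximum of `k - 1` tangent lines at `1/k, ..., (k-1)/k` — a convex
piecewise-linear underestimator solved exactly by the piecewise-linear
solver.  The reported objective is always the true loss at the returned
feasible point; the surrogate optimum (a certified lower bound on the
true optimum) is kept in diagnostics, giving the sandwich
`surrogate <= optimum <= reported`.  For beta-Lipschitz losses the
surrogate gap obeys `n * beta / k`.

*Known limitation.*  The bound is vacuous for count losses near the
boundary, and the even tangent grid has a concrete failure mode:
whenever a mutation's optimal frequency lies strictly inside
`(0, 1/k)` while `v >= 1`, the surrogate — whose first tangent sits at
`1/k` — snaps the solution to `f = 0`, where the clamped
log-likelihood costs about `-v ln(eps)` (~ 41 per variant read).  Two
regimes produce such mutations: observed VAFs below `1/k` (requires
depth `d > k`, so common at coverage above `k`), and trees whose clone
proportions are below `1/k` (mutation-level trees with `n > k`
vertices force this regardless of coverage).  In those regimes the
true-loss excess of PLA-50/100 over the optimum reaches tens of
percent even though the surrogate optimum itself stays within a
fraction of a percent of the true optimum — the sandwich is honest but
loose on its upper side.  The progressive variant repairs this: its
second round re-centers the tangent grid inside a shrunken box around
the first-round solution, resolving the boundary region adaptively; in
our benchmarks PPLA reproduces the reference optimum to ~1e-8
relative.  Prefer PPLA or ADMM whenever clone frequencies may fall
below `1/k`.

**PPLA(k, tau, sigma).**  `tau` rounds of PLA with `k` segments whose
tangent points are evenly spaced inside per-mutation boxes; after each
round the boxes re-center on the solution and shrink by `sigma`
(defaults `k = 10`, `tau = 3`, `sigma = 0.25`), and the best true-loss
iterate is returned.  The exact bound-update schedule is this package's
design; one round with boxes `[0, 1]` coincides with PLA-k.

## Reference solvers (tests only)

The production solvers are validated against general-purpose convex
optimization that shares no code with the dynamic program:
piecewise-linear losses against an epigraph LP (HiGHS); the l2 loss
against a sparse interior-point solve in frequency space refined by an
exact active-set step; count losses against an interior-point solve in
usage space (`f = B^T u`, bounds plus one simplex row, Hessian-vector
products), where the bound geometry avoids the ill-conditioning of the
clamped frequency box — a maxiter exit is accepted only when a
continuation run moves the objective by less than `1e-7` relative,
because boundary optima (`v = 0` or `v = d`) make the gradient
criterion unattainable even after the value has converged.  A brute
force lattice search covers `n <= 4`.

## The simulator

`simulate_instance` draws a tree (uniform attachment by default:
parent of vertex `i` uniform on `0..i-1`; optionally bounded
out-degree), per-sample clone proportions from a symmetric
`Dirichlet(concentration)` over `n + 1` components (the last being the
discarded normal fraction; default concentration 1), frequencies as
exact subtree sums, depths `d ~ Poisson(coverage)` (so zero-depth
mutations occur naturally and exercise the zero-loss path), and variant
reads binomially — or beta-binomially with precision `s` for
overdispersed data.  Fixed seeds give bit-identical instances.

What the generator emulates is the mixture structure and counting
noise the regression assumes; what it does not emulate: copy-number
aberrations, mutation-clustering error, sequencing error, or
correlated depths.  Tests passing on these instances certify the
optimization (feasibility, optimality, duality, approximation bounds),
not robustness to real-data artifacts upstream of the model.

Cluster summarization follows the two standard conventions: pooling
reads (`v' = sum v`, `d' = sum d`) or averaging VAFs
(`vaf' = mean(vaf)`, `d' = mean(d)`, `v' = vaf' d'`, non-integer
counts allowed since the binomial coefficient is dropped).

## Benchmark protocol and problem sizes

The bundled benchmark (`scripts/acceptance.py`) simulates 20 instances
(uniform-attachment trees, n alternating between 100 and 500, m = 3
samples, binomial reads at 100x coverage), solves every single-sample
subproblem with ADMM (`rho = 1`, `tol = 1e-6`, at most 1000
iterations), PLA-50 and PLA-100, and reports the maximum relative
excess of their objectives over the usage-space interior-point
reference, in percent.  Under these conditions the PLA excess is
dominated by the even-grid boundary pathology described above (the
surrogate lower bound stays tight; the true loss at the returned point
does not), and the ADMM excess by the iteration cap at `rho = 1` —
both are reported as measured.  The randomized
solver-vs-oracle equivalence suites run at n up to 60 (l2 and
piecewise-linear, 200 instances each); the subquadratic-scaling probe
runs the l2 solver at n in {250, 1000, 4000}; the coverage-recovery
check averages 8 seeds per coverage at n = 40.  These sizes were chosen
to make the full suite convenient to run routinely on a laptop-class
machine.

## Known limitations

* The dynamic programs store plain sorted arrays; the inductive merge
  costs O(size of subtree) per vertex, i.e. O(n * average depth)
  overall — subquadratic on random trees, quadratic on a path.  The
  polylogarithmic mergeable-structure variant would remove that worst
  case and is left as an optimization behind the same interface.
* ADMM uses a fixed penalty `rho`; no adaptive rescaling.
* PLA-k with even tangent grids degrades at coverage above ~`k` (see
  above); prefer PPLA or ADMM there.
* Copy-number effects must be corrected upstream; the model treats
  variant frequencies as descendant-cell-fraction estimates.
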