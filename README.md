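# treeppr

Regression of mutation frequencies on a fixed clonal tree.

Bulk DNA sequencing of a tumor measures, for each somatic mutation, a
variant read count `v` out of a total depth `d` — a noisy estimate of
the latent frequency `f` of the mutation in the sample.  Under the
infinite sites assumption the mutations evolve down a rooted *clonal
tree*, the sample is a mixture of clones, and a frequency vector is
realizable as a mixture exactly when it satisfies the **Sum
Condition**: `f_i >= sum of the children's frequencies` at every
vertex, with `f_root <= 1`.  Tree-search methods for tumor phylogeny
inference solve, thousands of times, the inner regression

```
minimize   L(f) = sum_i L_i(f_i)
subject to f in the Sum Condition polytope of T
```

for candidate trees `T` — this package solves that problem.  It is
aimed at developers of phylogeny inference pipelines and at anyone who
wants maximum-likelihood frequencies and clone proportions for a known
tree.

Solvers:

* **Exact tree-structured dual dynamic programming** for the weighted
  l2 loss `w_i (f_i - f~_i)^2` and for arbitrary convex
  piecewise-linear losses (l1 included): a bottom-up pass over concave
  dual value functions `J_i(gamma) = max_{a>=0} { h_i(a - gamma) +
  sum_children J_j(a) }` with `h_i(x) = min_f { L_i(f) - x f }`,
  followed by top-down recovery of frequencies, usages and a dual
  certificate with zero duality gap.
* **ADMM** for binomial / beta-binomial read-count likelihoods:
  alternates 1D proximal steps with the exact l2 solver as a
  projection onto the tree polytope.
* **PLA-k / PPLA**: tangent-line underestimators with `k` segments
  solved exactly by the piecewise-linear solver, optionally refined
  progressively in shrinking frequency boxes.

A seeded simulator generates trees, clone mixtures and read counts, so
everything here runs without external data.  See `docs/methods.md` for
the model, algorithms, and known limitations (in particular when to
prefer PPLA or ADMM over plain PLA-k).

## Worked example

A three-mutation star tree (mutations 1 and 2 both arise from founder
0) with observed frequencies `(0.2, 0.3, 0.3)` is infeasible: the
children sum to 0.6 but the founder is at 0.2.  The l2 regression
projects onto the polytope:

```python
import treeppr as tp

tree = tp.read_tree("0\t1\n0\t2")
res = tp.solve_l2(tree, tp.LossSpec.l2([0.2, 0.3, 0.3]))
print(res.objective)          # 0.053333333333333344
print(res.f)                  # [0.33333333 0.16666667 0.16666667]
print(res.u)                  # [5.55111512e-17 1.66666667e-01 1.66666667e-01]
print(res.diagnostics["dual_objective"])   # 0.05333333333333333
```

The optimum `4/75` raises the founder to `1/3` (exactly the children's
sum, so clone 0 has usage 0) and shrinks the children to `1/6`; the
dual certificate matches the primal objective, proving optimality.
One-third of the sample is unexplained by any clone — the inferred
normal-cell fraction.

From the shell, the same computation on files, plus a simulated
read-count instance solved under the binomial likelihood:

```
treeppr simulate --n 100 --m 3 --coverage 100 --seed 7 --outdir sim/
treeppr solve --tree sim/tree.txt --variant sim/V.tsv --total sim/D.tsv \
              --loss binomial --solver admm --output result.json
treeppr evaluate --result result.json --truth sim/truth.json
# {"frequency_rmse": 0.013412468636981405, "objective": 4031.012662657882}
```

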