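import numpy as np
import pytest

import treeppr as tp
from treeppr.reference_oracle import oracle_solve

from conftest import random_pwl_pieces, random_tree


def rel_err(a, b):
    return abs(a - b) / (1 + abs(b))


class TestSolveL2Examples:
    def test_star_projection(self, star3):
        res = tp.solve_l2(star3, tp.LossSpec.l2([0.2, 0.3, 0.3]))
        assert res.objective == pytest.approx(4 / 75)
        assert res.f == pytest.approx([1 / 3, 1 / 6, 1 / 6])

    def test_feasible_input_is_fixed_point(self, chain2):
        res = tp.solve_l2(chain2, tp.LossSpec.l2([0.9, 0.4]))
        assert res.objective == pytest.approx(0.0, abs=1e-15)
        assert res.f == pytest.approx([0.9, 0.4])

    def test_single_node_clips_to_one(self):
        res = tp.solve_l2(tp.ClonalTree.trivial(), tp.LossSpec.l2([1.5]))
        assert res.f[0] == pytest.approx(1.0)
        assert res.objective == pytest.approx(0.25)

    def test_rejects_wrong_family(self, chain2):
        with pytest.raises(ValueError):
            tp.solve_l2(chain2, tp.LossSpec.l1([0.2, 0.5]))


class TestSolvePwlExamples:
    def test_chain_l1(self, chain2):
        res = tp.solve_pwl(chain2, tp.LossSpec.l1([0.2, 0.5]))
        assert res.objective == pytest.approx(0.3)
        # optimum attained on f0 = f1 = c, c in [0.2, 0.5]
        assert res.f[0] == pytest.approx(res.f[1])
        assert 0.2 - 1e-9 <= res.f[0] <= 0.5 + 1e-9

    def test_star_l1(self, star3):
        res = tp.solve_pwl(star3, tp.LossSpec.l1([0.2, 0.3, 0.3]))
        assert res.objective == pytest.approx(0.4)

    def test_zero_loss_returns_deterministic_point(self, star3):
        pieces = [
            tp.PiecewiseLinearConvex(np.empty(0), np.array([0.0])) for _ in range(3)
        ]
        res1 = tp.solve_pwl(star3, tp.LossSpec.pwl(pieces))
        res2 = tp.solve_pwl(star3, tp.LossSpec.pwl(pieces))
        assert res1.objective == pytest.approx(0.0)
        np.testing.assert_array_equal(res1.f, res2.f)


class TestOracleEquivalence:
    def test_l2_random_instances(self, rng):
        for _ in range(40):
            n = int(rng.integers(1, 61))
            tree = random_tree(n, rng)
            spec = tp.LossSpec.l2(rng.uniform(0, 1, n), rng.uniform(0.2, 3.0, n))
            res = tp.solve_l2(tree, spec)
            ora = oracle_solve(tree, spec)
            assert rel_err(res.objective, ora.objective) < 1e-6
            assert tp.check_sum_condition(tree, res.f, tol=1e-6) == []
            assert res.u.min() >= 0 and res.u.sum() <= 1 + 1e-6

    def test_pwl_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 41))
            tree = random_tree(n, rng)
            spec = tp.LossSpec.pwl(random_pwl_pieces(n, rng))
            res = tp.solve_pwl(tree, spec)
            ora = oracle_solve(tree, spec)
            assert rel_err(res.objective, ora.objective) < 1e-6
            assert tp.check_sum_condition(tree, res.f, tol=1e-6) == []

    def test_l1_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 61))
            tree = random_tree(n, rng)
            spec = tp.LossSpec.l1(rng.uniform(0, 1, n))
            res = tp.solve_pwl(tree, spec)
            ora = oracle_solve(tree, spec)
            assert rel_err(res.objective, ora.objective) < 1e-6


class TestDuality:
    def test_strong_duality_l2(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 50))
            tree = random_tree(n, rng)
            spec = tp.LossSpec.l2(rng.uniform(0, 1, n), rng.uniform(0.5, 2.0, n))
            res = tp.solve_l2(tree, spec)
            d = tp.dual_objective(tree, spec, res.dual)
            assert abs(res.objective - d) <= 1e-8 * (1 + abs(res.objective))

    def test_strong_duality_pwl(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 40))
            tree = random_tree(n, rng)
            spec = tp.LossSpec.pwl(random_pwl_pieces(n, rng))
            res = tp.solve_pwl(tree, spec)
            d = tp.dual_objective(tree, spec, res.dual)
            assert abs(res.objective - d) <= 1e-8 * (1 + abs(res.objective))

    def test_dual_certificate_star_matches_primal(self, star3):
        spec = tp.LossSpec.l2([0.2, 0.3, 0.3])
        res = tp.solve_l2(star3, spec)
        assert tp.dual_objective(star3, spec, res.dual) == pytest.approx(4 / 75)

    def test_weak_duality_random_alpha(self, rng):
        """Any nonnegative multiplier vector lower-bounds the optimum."""
        for _ in range(10):
            n = int(rng.integers(2, 20))
            tree = random_tree(n, rng)
            spec = tp.LossSpec.l2(rng.uniform(0, 1, n))
            opt = tp.solve_l2(tree, spec).objective
            cert = tp.DualCertificate(
                float(rng.uniform(0, 1)), rng.uniform(0, 2, n)
            )
            assert tp.dual_objective(tree, spec, cert) <= opt + 1e-9

    def test_zero_alpha_gives_sum_of_minima(self, star3):
        spec = tp.LossSpec.l2([0.2, 0.3, 0.3])
        cert = tp.DualCertificate(0.0, np.zeros(3))
        assert tp.dual_objective(star3, spec, cert) == pytest.approx(0.0)

    def test_rejects_negative_alpha(self, star3):
        spec = tp.LossSpec.l2([0.2, 0.3, 0.3])
        with pytest.raises(ValueError):
            tp.dual_objective(star3, spec, tp.DualCertificate(0.0, np.array([0.0, -1.0, 0.0])))


class TestValueFunctionRepresentations:
    """Validate the closed-form value-function representations against a
    slow numeric maximization of the dual recursion on a grid."""

    def _numeric_J(self, tree, hhat_vals, gamma_grid, alpha_grid):
        # hhat_vals[i]: callable z -> hhat_i(z), vectorized
        J = {}
        for i in tree.postorder():
            child = np.zeros_like(alpha_grid)
            for j in tree.children[i]:
                child += np.interp(alpha_grid, gamma_grid, J[j])
            M = hhat_vals[i](gamma_grid[:, None] - alpha_grid[None, :]) + child[None, :]
            J[i] = M.max(axis=1)
        return J

    def test_l2_derivative_matches_numeric_dp(self, rng):
        gamma_grid = np.linspace(-1, 8, 1801)
        alpha_grid = gamma_grid[gamma_grid >= 0]
        for _ in range(4):
            n = int(rng.integers(2, 7))
            tree = random_tree(n, rng)
            ft = rng.uniform(0, 1, n)
            w = rng.uniform(0.5, 2.0, n)

            def make_hhat(i):
                # hhat(z) = h(-z) = -z^2/(4w) + z*ft
                return lambda z, i=i: -(z**2) / (4 * w[i]) + z * ft[i]

            hhats = [make_hhat(i) for i in range(n)]
            J = self._numeric_J(tree, hhats, gamma_grid, alpha_grid)
            # the solver's stored representation of J_root'
            from treeppr.tsddp_solvers import _pl_eval

            import treeppr.tsddp_solvers as mod

            # numeric derivative of J_root vs analytic at probe points
            d_num = np.gradient(J[tree.root], gamma_grid)
            # reconstruct representation via the module internals
            nodes = self._l2_nodes(mod, tree, w, ft)
            root = nodes[tree.root]
            for g in (0.1, 0.5, 1.2, 3.0, 6.0):
                mine = float(
                    _pl_eval(root.jxs, root.jys, root.jsl, root.jsr, np.array([g]))[0]
                )
                ref = float(np.interp(g, gamma_grid, d_num))
                assert mine == pytest.approx(ref, abs=0.02)

    @staticmethod
    def _l2_nodes(mod, tree, w, ft):
        spec = tp.LossSpec.l2(ft, w)
        # run the bottom-up pass only, by calling solve_l2 and then
        # rebuilding: simplest is to duplicate the pass via the public
        # solver; instead probe the internals through a fresh solve
        nodes = [mod._L2Node() for _ in range(tree.n)]
        for i in range(tree.n):
            nodes[i].w = float(w[i])
            nodes[i].ft = float(ft[i])
        for i in tree.postorder():
            node = nodes[i]
            kids = tree.children[i]
            if not kids:
                node.jxs = np.array([2 * node.w * node.ft])
                node.jys = np.array([0.0])
                node.jsl = -1.0 / (2 * node.w)
                node.jsr = 0.0
                continue
            all_x = np.unique(np.concatenate([nodes[j].jxs for j in kids]))
            ys = np.zeros_like(all_x)
            sl = sr = 0.0
            for j in kids:
                k = nodes[j]
                ys = ys + mod._pl_eval(k.jxs, k.jys, k.jsl, k.jsr, all_x)
                sl += k.jsl
                sr += k.jsr
            pos = all_x > 0
            c0 = float(mod._pl_eval(all_x, ys, sl, sr, np.array([0.0]))[0])
            xs_c = np.concatenate(([0.0], all_x[pos]))
            ys_c = np.concatenate(([c0], ys[pos]))
            node.xs_c, node.ys_c, node.sr_c = xs_c, ys_c, sr
            gvals = xs_c + 2 * node.w * (node.ft - ys_c)
            node.gvals = gvals
            node.jxs = gvals
            node.jys = ys_c
            node.jsl = -1.0 / (2 * node.w)
            node.jsr = sr / (1.0 - 2 * node.w * sr)
        return nodes

    def test_pwl_derivative_matches_numeric_dp(self, rng):
        from treeppr.tsddp_solvers import (
            _hhat_derivative,
            _step_restrict,
            _step_sum,
            _supconv_derivative,
        )

        gamma_grid = np.linspace(-2, 8, 3001)
        alpha_grid = gamma_grid[gamma_grid >= 0]
        for _ in range(4):
            n = int(rng.integers(2, 6))
            tree = random_tree(n, rng)
            pieces = random_pwl_pieces(n, rng)

            zg = np.linspace(gamma_grid[0] - alpha_grid[-1] - 0.1, gamma_grid[-1] + 0.1, 4001)

            def make_hhat(piece):
                base = np.empty(zg.size)
                for t, zz in enumerate(zg):
                    lo, _ = piece.argmin_interval(tilt=-zz)
                    base[t] = float(piece(lo)) + zz * lo
                return lambda z: np.interp(z, zg, base)

            hhats = [make_hhat(p) for p in pieces]
            J = self._numeric_J(tree, hhats, gamma_grid, alpha_grid)
            hs = [_hhat_derivative(p) for p in pieces]
            j_all = [None] * n
            for i in tree.postorder():
                kids = tree.children[i]
                cs = _step_restrict(_step_sum([j_all[j] for j in kids])) if kids else None
                j_all[i] = _supconv_derivative(hs[i], cs)
            d_num = np.gradient(J[tree.root], gamma_grid)
            fn = j_all[tree.root]
            for g in (0.11, 0.53, 1.27, 2.9, 5.1):
                mine = fn.vs[np.searchsorted(fn.xs, g, side="right")]
                ref = float(np.interp(g, gamma_grid, d_num))
                # step derivative vs smoothed finite difference
                assert mine == pytest.approx(ref, abs=0.05)


class TestStructure:
    def test_value_function_concavity(self, rng):
        """Sampled three-point concavity of every constructed value
        function (checked through its non-increasing step derivative)."""
        from treeppr.losses import LossSpec
        from treeppr.tsddp_solvers import (
            _hhat_derivative,
            _step_restrict,
            _step_sum,
            _supconv_derivative,
        )

        for _ in range(10):
            n = int(rng.integers(2, 15))
            tree = random_tree(n, rng)
            pieces = random_pwl_pieces(n, rng)
            hs = [_hhat_derivative(p) for p in pieces]
            j_all = [None] * n
            for i in tree.postorder():
                kids = tree.children[i]
                cs = _step_restrict(_step_sum([j_all[j] for j in kids])) if kids else None
                j_all[i] = _supconv_derivative(hs[i], cs)
            for fn in j_all:
                assert np.all(np.diff(fn.vs) < 0)  # strictly decreasing slopes
                if fn.xs.size:
                    assert np.all(np.diff(fn.xs) > 0)

    def test_separability_over_samples(self, rng):
        """Summed per-sample objectives equal the block optimum."""
        n = 12
        tree = random_tree(n, rng)
        inst = tp.simulate_instance(
            tp.SimulationConfig(n=n, m=3, coverage=80, seed=5)
        )
        total = 0.0
        for p in range(3):
            ft = np.clip(inst.V[p] / np.maximum(inst.D[p], 1), 0, 1)
            total += tp.solve_l2(inst.tree, tp.LossSpec.l2(ft)).objective
        block = sum(
            oracle_solve(
                inst.tree,
                tp.LossSpec.l2(np.clip(inst.V[p] / np.maximum(inst.D[p], 1), 0, 1)),
            ).objective
            for p in range(3)
        )
        assert total == pytest.approx(block, rel=1e-6, abs=1e-9)

    def test_deterministic_output(self, rng):
        n = 30
        tree = random_tree(n, rng)
        spec = tp.LossSpec.l1(rng.uniform(0, 1, n))
        r1 = tp.solve_pwl(tree, spec)
        r2 = tp.solve_pwl(tree, spec)
        np.testing.assert_array_equal(r1.f, r2.f)
        np.testing.assert_array_equal(r1.dual.alpha, r2.dual.alpha)
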