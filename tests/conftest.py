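import numpy as np
import pytest

import treeppr as tp


def random_tree(n: int, rng: np.random.Generator) -> tp.ClonalTree:
    """Uniform-attachment random tree on n vertices."""
    if n == 1:
        return tp.ClonalTree.trivial()
    parent = [-1] + [int(rng.integers(0, i)) for i in range(1, n)]
    return tp.ClonalTree.from_parent_array(parent)


def random_pwl_pieces(n: int, rng: np.random.Generator, kmax: int = 6):
    """Random convex piecewise-linear losses on [0, 1]."""
    pieces = []
    for _ in range(n):
        k = int(rng.integers(1, kmax))
        slopes = np.sort(rng.uniform(-3, 3, k)) + np.arange(k) * 1e-3
        bp = np.sort(rng.uniform(0.05, 0.95, k - 1)) + np.arange(max(k - 1, 0)) * 1e-6
        pieces.append(
            tp.PiecewiseLinearConvex(bp, slopes, anchor=(0.5, float(rng.uniform(-1, 1))))
        )
    return pieces


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def star3():
    return tp.read_tree("0\t1\n0\t2")


@pytest.fixture
def chain2():
    return tp.read_tree("0\t1")
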