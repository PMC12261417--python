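"""Simulator for clonal trees, clone mixtures and bulk read counts.

Emulates the generative structure the regression assumes: a rooted
clonal tree, per-sample clone proportions drawn from a symmetric
Dirichlet (with one extra component for the normal-cell fraction), true
mutation frequencies given exactly by subtree sums, sequencing depth
drawn per mutation from a Poisson, and variant reads drawn binomially
(or beta-binomially, for overdispersed data) around the true frequency.

Poisson depth means zero-coverage mutations occur naturally at low
coverage, exercising the zero-information loss path.  What the
simulator deliberately does not model: copy-number aberrations,
mutation clustering error, sample contamination.

Also provides the two standard conventions for summarizing a mutation
cluster as a single pseudo-mutation: read pooling and VAF averaging
(the latter keeps per-mutation variance comparable and may produce
non-integer variant counts, which the count losses accept since the
binomial coefficient is dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tree_core import ClonalTree, frequency_from_usage

__all__ = ["SimulationConfig", "SimulatedInstance", "simulate_instance", "cluster_summarize"]


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings.

    ``coverage`` is the expected total reads per mutation;
    ``concentration`` the symmetric Dirichlet parameter over the n + 1
    mixture components (clones plus normal); ``tree_model`` one of
    ``"uniform_attachment"`` (parent of vertex i uniform over 0..i-1) or
    ``"bounded_outdegree"`` with ``max_children``; ``read_model`` one of
    ``"binomial"`` or ``"betabinomial"`` with precision ``s``.
    """

    n: int = 100
    m: int = 3
    coverage: float = 100.0
    tree_model: str = "uniform_attachment"
    max_children: int = 3
    concentration: float = 1.0
    read_model: str = "binomial"
    s: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.m < 1:
            raise ValueError("n and m must be at least 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.tree_model not in ("uniform_attachment", "bounded_outdegree"):
            raise ValueError(f"unknown tree model {self.tree_model!r}")
        if self.read_model not in ("binomial", "betabinomial"):
            raise ValueError(f"unknown read model {self.read_model!r}")
        if self.s <= 0:
            raise ValueError("beta-binomial precision must be positive")


@dataclass(frozen=True)
class SimulatedInstance:
    """Ground truth plus observed counts: ``F`` equals the row-wise
    subtree sums of ``U`` exactly, and ``0 <= V <= D`` elementwise."""

    tree: ClonalTree
    U: np.ndarray
    F: np.ndarray
    V: np.ndarray
    D: np.ndarray
    config: SimulationConfig = field(repr=False, default=SimulationConfig())


def _random_tree(cfg: SimulationConfig, rng: np.random.Generator) -> ClonalTree:
    n = cfg.n
    if n == 1:
        return ClonalTree.trivial()
    parent = [-1] * n
    if cfg.tree_model == "uniform_attachment":
        for i in range(1, n):
            parent[i] = int(rng.integers(0, i))
    else:
        child_count = [0] * n
        for i in range(1, n):
            eligible = [v for v in range(i) if child_count[v] < cfg.max_children]
            p = int(eligible[rng.integers(0, len(eligible))])
            parent[i] = p
            child_count[p] += 1
    return ClonalTree.from_parent_array(parent)


def simulate_instance(cfg: SimulationConfig) -> SimulatedInstance:
    """Draw one instance; a fixed seed gives bit-identical output."""
    rng = np.random.default_rng(cfg.seed)
    tree = _random_tree(cfg, rng)
    n, m = cfg.n, cfg.m
    # n + 1 Dirichlet components; the last is the discarded normal fraction
    U_full = rng.dirichlet(np.full(n + 1, cfg.concentration), size=m)
    U = U_full[:, :n]
    F = np.vstack([frequency_from_usage(tree, U[p]) for p in range(m)])
    D = rng.poisson(cfg.coverage, size=(m, n))
    if cfg.read_model == "binomial":
        V = rng.binomial(D, F)
    else:
        a = F * cfg.s
        b = (1 - F) * cfg.s
        # degenerate ends: Beta(0, s) -> 0, Beta(s, 0) -> 1
        p = np.where(a <= 0, 0.0, np.where(b <= 0, 1.0, rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))))
        V = rng.binomial(D, p)
    return SimulatedInstance(tree=tree, U=U, F=F, V=V, D=D, config=cfg)


def cluster_summarize(
    V: np.ndarray,
    D: np.ndarray,
    clusters: Sequence[Sequence[int]],
    mode: str = "pool",
) -> tuple[np.ndarray, np.ndarray]:
    """Summarize mutation clusters as single pseudo-mutations.

    ``pool`` sums variant and total reads across the cluster;
    ``average`` averages the member VAFs and depths and sets
    ``v' = vaf' * d'`` (non-integer counts permitted).  Clusters must be
    disjoint, nonempty lists of column indices; the returned matrices
    have one column per cluster, in input order.
    """
    V = np.asarray(V, dtype=float)
    D = np.asarray(D, dtype=float)
    if V.shape != D.shape:
        raise ValueError("V and D must have the same shape")
    if mode not in ("pool", "average"):
        raise ValueError(f"unknown mode {mode!r}")
    seen: set[int] = set()
    for c in clusters:
        if len(c) == 0:
            raise ValueError("empty cluster")
        overlap = seen.intersection(c)
        if overlap:
            raise ValueError(f"clusters overlap on mutations {sorted(overlap)}")
        seen.update(c)
    m = V.shape[0]
    Vp = np.empty((m, len(clusters)))
    Dp = np.empty((m, len(clusters)))
    for k, c in enumerate(clusters):
        idx = list(c)
        if mode == "pool":
            Vp[:, k] = V[:, idx].sum(axis=1)
            Dp[:, k] = D[:, idx].sum(axis=1)
        else:
            d_sub = D[:, idx]
            if np.any(d_sub == 0):
                raise ValueError(
                    "average mode is undefined when a member has zero depth; "
                    "use pool mode"
                )
            vaf = (V[:, idx] / d_sub).mean(axis=1)
            Dp[:, k] = d_sub.mean(axis=1)
            Vp[:, k] = vaf * Dp[:, k]
    return Vp, Dp
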