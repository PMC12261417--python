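"""Rooted clonal trees and the perfect-phylogeny mixture constraint.

A clonal tree on ``n`` mutations identifies each vertex (clone) with the
mutation gained on the edge into it.  The clonal matrix ``B`` has
``b[i, j] = 1`` iff mutation ``j`` lies on the root-to-``i`` path, so a
sample's frequency vector ``f`` and clone-usage vector ``u`` are linked by
``f = B^T u``: the frequency of a mutation is the total proportion of
clones in its subtree.  A frequency vector is realizable as a nonnegative
clone mixture iff it satisfies the Sum Condition (``f_i`` at least the sum
of its children's frequencies) and ``f_root <= 1``; the slack
``1 - sum(u)`` is the normal-cell fraction.

Vertex ids are dense 0-based integers and double as column indices of the
read-count matrices.  The root is inferred (the unique id never appearing
as a child), never declared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable

import numpy as np

__all__ = [
    "ClonalTree",
    "TreeFormatError",
    "InfeasibleFrequencyError",
    "read_tree",
    "write_tree",
    "build_clonal_matrix",
    "check_sum_condition",
    "usage_from_frequency",
    "frequency_from_usage",
]

#: sentinel parent id of the root vertex
NO_PARENT = -1

#: default feasibility tolerance for solver output
DEFAULT_TOL = 1e-6


class TreeFormatError(ValueError):
    """Raised when an edge list does not describe a valid rooted tree."""


class InfeasibleFrequencyError(ValueError):
    """Raised when a frequency vector violates the Sum Condition."""


@dataclass(frozen=True)
class ClonalTree:
    """A rooted tree on vertices ``{0, ..., n-1}``.

    Attributes
    ----------
    n:
        Number of vertices (mutations / clones).
    parent:
        ``parent[i]`` is the parent of vertex ``i``; the root stores
        :data:`NO_PARENT`.
    children:
        ``children[i]`` lists the children of ``i`` in ascending order,
        so traversals and tie-breaks are deterministic across runs.
    root:
        The unique vertex with no parent.
    """

    n: int
    parent: tuple[int, ...]
    children: tuple[tuple[int, ...], ...]
    root: int
    # vertices in root-first (BFS) order; cached for linear-time passes
    _order: tuple[int, ...] = field(repr=False, default=())

    @staticmethod
    def from_edges(edges: Iterable[tuple[int, int]]) -> "ClonalTree":
        """Build and validate a tree from (parent, child) pairs."""
        edges = list(edges)
        if not edges:
            # single-vertex tree has no edges; callers wanting n=1 use
            # ClonalTree.trivial() instead
            raise TreeFormatError("empty edge list")
        ids = sorted({v for e in edges for v in e})
        n = len(ids)
        if ids != list(range(n)):
            raise TreeFormatError(
                f"vertex ids must be exactly 0..{n - 1}, got {ids}"
            )
        parent = [NO_PARENT] * n
        for p, c in edges:
            if parent[c] != NO_PARENT:
                raise TreeFormatError(
                    f"vertex {c} has two parents ({parent[c]} and {p})"
                )
            parent[c] = p
        roots = [v for v in range(n) if parent[v] == NO_PARENT]
        if len(roots) != 1:
            raise TreeFormatError(
                f"expected exactly one root, found {len(roots)}: {roots}"
            )
        return ClonalTree._finish(n, parent, roots[0])

    @staticmethod
    def from_parent_array(parent: Iterable[int]) -> "ClonalTree":
        """Build from a parent array using :data:`NO_PARENT` for the root."""
        parent = [int(p) for p in parent]
        n = len(parent)
        roots = [v for v in range(n) if parent[v] == NO_PARENT]
        if len(roots) != 1:
            raise TreeFormatError(f"expected one root, found {roots}")
        for v, p in enumerate(parent):
            if p != NO_PARENT and not 0 <= p < n:
                raise TreeFormatError(f"parent of {v} out of range: {p}")
        return ClonalTree._finish(n, parent, roots[0])

    @staticmethod
    def trivial() -> "ClonalTree":
        """The single-vertex tree."""
        return ClonalTree(1, (NO_PARENT,), ((),), 0, (0,))

    @staticmethod
    def _finish(n: int, parent: list[int], root: int) -> "ClonalTree":
        children: list[list[int]] = [[] for _ in range(n)]
        for v in range(n):
            if v != root:
                children[parent[v]].append(v)
        # BFS from the root; detects cycles/disconnection by vertex count
        order: list[int] = [root]
        head = 0
        while head < len(order):
            v = order[head]
            head += 1
            order.extend(children[v])
        if len(order) != n:
            missing = sorted(set(range(n)) - set(order))
            raise TreeFormatError(
                f"cycle or disconnected component involving vertices {missing}"
            )
        return ClonalTree(
            n,
            tuple(parent),
            tuple(tuple(sorted(c)) for c in children),
            root,
            tuple(order),
        )

    @property
    def bfs_order(self) -> tuple[int, ...]:
        """Vertices in root-first order (parents before children)."""
        return self._order

    def postorder(self) -> tuple[int, ...]:
        """Vertices with every child before its parent."""
        return tuple(reversed(self._order))


def read_tree(stream: IO[str] | str) -> ClonalTree:
    """Parse a tree from ``parent<TAB>child`` lines; ``#`` starts a comment.

    The root is the unique id that never appears as a child.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    edges: list[tuple[int, int]] = []
    seen_children: set[int] = set()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise TreeFormatError(
                f"line {lineno}: expected 'parent<TAB>child', got {raw!r}"
            )
        try:
            p, c = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise TreeFormatError(f"line {lineno}: non-integer id in {raw!r}") from exc
        if c in seen_children:
            raise TreeFormatError(f"line {lineno}: duplicate child {c}")
        seen_children.add(c)
        edges.append((p, c))
    return ClonalTree.from_edges(edges)


def write_tree(tree: ClonalTree, stream: IO[str]) -> None:
    """Emit the same ``parent<TAB>child`` dialect read by :func:`read_tree`."""
    for v in tree.bfs_order:
        if v != tree.root:
            stream.write(f"{tree.parent[v]}\t{v}\n")


def build_clonal_matrix(tree: ClonalTree) -> np.ndarray:
    """The n-by-n binary matrix with ``B[i, j] = 1`` iff ``j`` is an
    ancestor-or-self of ``i``."""
    n = tree.n
    B = np.zeros((n, n), dtype=np.int8)
    for v in tree.bfs_order:
        if v != tree.root:
            B[v] = B[tree.parent[v]]
        B[v, v] = 1
    return B


def check_sum_condition(
    tree: ClonalTree, f: np.ndarray, tol: float = 0.0
) -> list[tuple[int, str, float]]:
    """List all Sum Condition violations of ``f`` on ``tree``.

    Returns tuples ``(vertex, kind, deficit)`` where ``kind`` is ``"sc"``
    for ``f_i < sum(children) - tol`` (for a leaf this reduces to a
    nonnegativity check) and ``"root"`` for ``f_root > 1 + tol``.  An
    empty list means ``f`` is realizable as a clone mixture.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (tree.n,):
        raise ValueError(f"expected frequency vector of length {tree.n}, got {f.shape}")
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    violations: list[tuple[int, str, float]] = []
    for i in range(tree.n):
        child_sum = float(sum(f[j] for j in tree.children[i]))
        if f[i] < child_sum - tol:
            violations.append((i, "sc", child_sum - float(f[i])))
    if f[tree.root] > 1 + tol:
        violations.append((tree.root, "root", float(f[tree.root]) - 1.0))
    return violations


def usage_from_frequency(
    tree: ClonalTree, f: np.ndarray, tol: float = DEFAULT_TOL
) -> np.ndarray:
    """Invert ``f = B^T u`` in one traversal: ``u_i = f_i - sum(children)``.

    Negative entries within ``tol`` (solver round-off) are clamped to 0;
    larger Sum Condition violations raise :class:`InfeasibleFrequencyError`.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (tree.n,):
        raise ValueError(f"expected frequency vector of length {tree.n}, got {f.shape}")
    u = f.copy()
    for i in range(tree.n):
        for j in tree.children[i]:
            u[i] -= f[j]
    if u.min(initial=0.0) < -tol or f[tree.root] > 1 + tol:
        viol = check_sum_condition(tree, f, tol)
        raise InfeasibleFrequencyError(
            f"frequency vector violates the Sum Condition beyond tol={tol}: {viol}"
        )
    np.clip(u, 0.0, None, out=u)
    return u


def frequency_from_usage(tree: ClonalTree, u: np.ndarray) -> np.ndarray:
    """Subtree sums ``f_i = sum_{j in D(i)} u_j`` in one post-order pass."""
    u = np.asarray(u, dtype=float)
    if u.shape != (tree.n,):
        raise ValueError(f"expected usage vector of length {tree.n}, got {u.shape}")
    if u.min(initial=0.0) < 0:
        raise ValueError("usage vector must be nonnegative")
    f = u.copy()
    for i in tree.postorder():
        p = tree.parent[i]
        if p != NO_PARENT:
            f[p] += f[i]
    return f
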