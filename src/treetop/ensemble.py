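"""Sampling an ensemble of minimum spanning trees over the Voronoi partitions.

Each tree draws one cell uniformly at random from every Voronoi partition
and joins the k sampled cells by a minimum spanning tree; edges are
recorded against the node indices, weighted by the data-space distance
between the sampled cells. The superposition of all trees forms a "union"
graph carrying per-edge occurrence frequencies and mean lengths, which may
contain cycles and is pruned at the largest frequency threshold that keeps
it connected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nodes import ReferenceNodeSet
from .preprocess import CellMatrix, distance_matrix

__all__ = [
    "TreeSample",
    "TreeEnsemble",
    "UnionGraph",
    "minimum_spanning_tree",
    "sample_tree",
    "build_ensemble",
    "union_graph",
    "prune_union_graph",
]


@dataclass
class TreeSample:
    """One spanning tree over the k reference nodes."""

    edges: list[tuple[int, int, float]]  # (node_i < node_j, weight)
    sampled_cell_indices: np.ndarray  # (k,) full-matrix row of the cell drawn per partition

    @property
    def k(self) -> int:
        return len(self.edges) + 1

    def adjacency(self) -> list[list[tuple[int, float]]]:
        adj: list[list[tuple[int, float]]] = [[] for _ in range(self.k)]
        for i, j, w in self.edges:
            adj[i].append((j, w))
            adj[j].append((i, w))
        return adj


@dataclass
class TreeEnsemble:
    trees: list[TreeSample]
    nodes: ReferenceNodeSet

    @property
    def n(self) -> int:
        return len(self.trees)

    @property
    def k(self) -> int:
        return self.nodes.k


@dataclass
class UnionGraph:
    """Superposition of ensemble trees: frequency and mean length per edge."""

    k: int
    edges: list[tuple[int, int, float, float]]  # (i, j, frequency, mean_distance)

    def is_connected(self) -> bool:
        return _connected(self.k, [(i, j) for i, j, _, _ in self.edges])


def _connected(k: int, edges: list[tuple[int, int]]) -> bool:
    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    n_comp = k
    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            n_comp -= 1
    return n_comp == 1


def minimum_spanning_tree(dist: np.ndarray) -> list[tuple[int, int, float]]:
    """Prim's algorithm with deterministic lowest-index tie-breaking.

    ``dist`` must be a square symmetric matrix with zero diagonal and
    finite entries. Returns k-1 edges as ``(i, j, weight)`` with ``i < j``,
    sorted lexicographically.
    """
    dist = np.asarray(dist, dtype=float)
    k = dist.shape[0]
    if dist.ndim != 2 or dist.shape[1] != k:
        raise ValueError("distance matrix must be square")
    if not np.isfinite(dist).all():
        raise ValueError("distance matrix contains non-finite entries")
    if k == 1:
        return []
    in_tree = np.zeros(k, dtype=bool)
    in_tree[0] = True
    best = dist[0].copy()
    best_parent = np.zeros(k, dtype=int)
    best[0] = np.inf
    edges: list[tuple[int, int, float]] = []
    for _ in range(k - 1):
        nxt = int(np.argmin(best))  # argmin returns the first minimum: lowest index
        a, b = int(best_parent[nxt]), nxt
        edges.append((min(a, b), max(a, b), float(dist[a, b])))
        in_tree[nxt] = True
        improve = dist[nxt] < best
        improve &= ~in_tree
        best_parent[improve] = nxt
        best[improve] = dist[nxt][improve]
        best[nxt] = np.inf
    edges.sort()
    return edges


def sample_tree(
    matrix: CellMatrix,
    nodes: ReferenceNodeSet,
    metric: str = "l1",
    seed: int = 0,
    _members: list[np.ndarray] | None = None,
) -> TreeSample:
    """Draw one cell per partition uniformly at random and join them by an MST."""
    rng = np.random.default_rng(seed)
    members = nodes.partition_members() if _members is None else _members
    sampled = np.array([m[rng.integers(len(m))] for m in members])
    d = distance_matrix(matrix.values[sampled], matrix.values[sampled], metric=metric)
    return TreeSample(edges=minimum_spanning_tree(d), sampled_cell_indices=sampled)


def build_ensemble(
    matrix: CellMatrix,
    nodes: ReferenceNodeSet,
    n_trees: int = 1000,
    metric: str = "l1",
    seed: int = 0,
) -> TreeEnsemble:
    """Sample ``n_trees`` independent trees; tree t uses seed ``seed + t``."""
    if n_trees < 1:
        raise ValueError("n_trees must be at least 1")
    members = nodes.partition_members()
    trees = [
        sample_tree(matrix, nodes, metric=metric, seed=seed + t, _members=members)
        for t in range(n_trees)
    ]
    return TreeEnsemble(trees=trees, nodes=nodes)


def union_graph(ensemble: TreeEnsemble) -> UnionGraph:
    """Mean over all edges of all trees: occurrence frequency and mean length."""
    if ensemble.n == 0:
        raise ValueError("empty ensemble")
    counts: dict[tuple[int, int], int] = {}
    sums: dict[tuple[int, int], float] = {}
    for tree in ensemble.trees:
        for i, j, w in tree.edges:
            key = (i, j)
            counts[key] = counts.get(key, 0) + 1
            sums[key] = sums.get(key, 0.0) + w
    n = ensemble.n
    edges = [
        (i, j, counts[(i, j)] / n, sums[(i, j)] / counts[(i, j)])
        for (i, j) in sorted(counts)
    ]
    return UnionGraph(k=ensemble.k, edges=edges)


def prune_union_graph(graph: UnionGraph) -> UnionGraph:
    """Drop low-frequency edges at the maximum threshold keeping connectivity."""
    if not graph.is_connected():
        raise ValueError("union graph must be connected before pruning")
    freqs = sorted({f for _, _, f, _ in graph.edges}, reverse=True)
    for t in freqs:
        kept = [(i, j) for i, j, f, _ in graph.edges if f >= t]
        if _connected(graph.k, kept):
            return UnionGraph(
                k=graph.k, edges=[e for e in graph.edges if e[2] >= t]
            )
    raise AssertionError("unreachable: the full edge set is connected")
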