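"""Branch-point statistics over a tree ensemble.

The branching score of a candidate node x asks: if every tree in the
ensemble is cut at x, how consistently do the remaining reference nodes
fall into three or more groups? Cutting one tree at x partitions the other
nodes into the connected components ("branches") left behind; accumulating
co-branch indicators over trees yields the consistency matrix B_x, whose
(i, j) entry is the proportion of trees in which i and j landed in the
same branch. Single-linkage clustering of B_x (as a similarity) is cut at
a grid of thresholds p_cut, and the raw branching score is the mean, over
thresholds, of the total size of the third-largest and smaller clusters —
large exactly when cutting at x reproducibly yields at least three
branches. Summing the third-largest *and smaller* clusters (rather than
the third alone) keeps multifurcations visible.

A cluster must contain at least two reference nodes to count as a branch.
Without this convention the score is dominated by a shattering artifact:
whenever the consistency matrix saturates below 1 (as it does for any
noisy, non-branching dataset — e.g. an isotropic Gaussian cloud, where
most node pairs share the giant component in ~3/4 of trees), every
threshold above that saturation level splits the dendrogram into k-1
singletons, each of which would be counted toward the branch total. That
artifact would assign near-maximal scores to structureless data and
swamp the statistic; one isolated reference node is not evidence of a
branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import f_oneway

from .ensemble import TreeEnsemble, TreeSample

__all__ = [
    "DEFAULT_THRESHOLDS",
    "ConsistencyMatrix",
    "BranchingResult",
    "cut_tree_at_node",
    "consistency_matrix",
    "raw_branching_score",
    "score_all_nodes",
    "mean_tree_distance",
    "marker_anova",
    "normalized_mutual_information",
]

#: p_cut grid 0.01, 0.02, ..., 0.99 — the endpoints 0 and 1 are degenerate
DEFAULT_THRESHOLDS: np.ndarray = np.round(np.arange(1, 100) / 100.0, 2)

#: branch label given to cells assigned to the branch-point node itself
BRANCH_POINT_LABEL = -1


@dataclass
class ConsistencyMatrix:
    """Pairwise co-branch probabilities among the nodes other than ``node_x``."""

    node_x: int
    others: np.ndarray  # (k-1,) node indices
    B: np.ndarray  # (k-1, k-1) symmetric, entries in [0, 1], unit diagonal


@dataclass
class BranchingResult:
    """Raw scores for every node plus the reported branch point and branches."""

    raw_scores: np.ndarray  # (k,) in units of reference-node counts
    branch_node: int
    best_pcut: float
    node_branches: np.ndarray  # (k,) branch id per node; BRANCH_POINT_LABEL at branch_node
    cell_branches: np.ndarray  # per retained cell (nodes order); BRANCH_POINT_LABEL allowed
    retained_indices: np.ndarray  # full-matrix rows the cell_branches refer to
    relative_score: Optional[float] = None
    b_ref: Optional[float] = None
    reference_params: Optional[tuple] = None
    extras: dict = field(default_factory=dict)

    @property
    def n_branches(self) -> int:
        return int(self.node_branches.max()) + 1

    @property
    def b_max(self) -> float:
        return float(self.raw_scores.max())


def cut_tree_at_node(tree: TreeSample, x: int) -> np.ndarray:
    """Branch labels induced by removing node ``x`` from one tree.

    Returns a length-k integer array; entry ``x`` is -1, every other node
    carries the id (0-based, in neighbour order of x) of the connected
    component it falls into after x and its incident edges are removed.
    The number of components equals the degree of x.
    """
    adj = tree.adjacency()
    k = tree.k
    if not 0 <= x < k:
        raise ValueError(f"node {x} not in tree with {k} nodes")
    labels = np.full(k, -1, dtype=np.int32)
    comp = 0
    for start, _ in adj[x]:
        if labels[start] != -1:
            continue
        stack = [start]
        labels[start] = comp
        while stack:
            u = stack.pop()
            for v, _ in adj[u]:
                if v != x and labels[v] == -1:
                    labels[v] = comp
                    stack.append(v)
        comp += 1
    return labels


def _cut_labels_all_nodes(tree: TreeSample) -> np.ndarray:
    """Row x = cut_tree_at_node(tree, x); shape (k, k)."""
    k = tree.k
    out = np.empty((k, k), dtype=np.int32)
    for x in range(k):
        out[x] = cut_tree_at_node(tree, x)
    return out


def _co_branch_counts(ensemble: TreeEnsemble) -> np.ndarray:
    """(k, k, k) counts: entry [x, i, j] = #trees with i, j in the same branch after cutting at x."""
    k = ensemble.k
    counts = np.zeros((k, k, k), dtype=np.int32)
    for tree in ensemble.trees:
        labels = _cut_labels_all_nodes(tree)
        counts += labels[:, :, None] == labels[:, None, :]
    return counts


def consistency_matrix(ensemble: TreeEnsemble, x: int) -> ConsistencyMatrix:
    """Co-branch probability matrix B_x over the other k-1 nodes."""
    k = ensemble.k
    if not 0 <= x < k:
        raise ValueError(f"node {x} out of range")
    counts = np.zeros((k, k), dtype=np.int64)
    for tree in ensemble.trees:
        labels = cut_tree_at_node(tree, x)
        counts += labels[:, None] == labels[None, :]
    others = np.array([i for i in range(k) if i != x])
    b = counts[np.ix_(others, others)] / ensemble.n
    np.fill_diagonal(b, 1.0)
    return ConsistencyMatrix(node_x=x, others=others, B=b)


def _cluster_sizes_over_thresholds(
    b: np.ndarray, thresholds: np.ndarray
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per threshold: branch-cluster total (sum of 3rd-largest and smaller sizes)
    and the flat cluster labels."""
    m = b.shape[0]
    diss = 1.0 - np.clip(b, 0.0, 1.0)
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="single")
    branch_totals = np.empty(len(thresholds))
    all_labels: list[np.ndarray] = []
    for t_i, pcut in enumerate(thresholds):
        labels = fcluster(z, t=1.0 - pcut, criterion="distance")
        sizes = _branch_sizes(labels)
        branch_totals[t_i] = sizes[2:].sum() if len(sizes) > 2 else 0
        all_labels.append(labels)
    return branch_totals, all_labels


def _branch_sizes(labels: np.ndarray) -> np.ndarray:
    """Cluster sizes, descending, singletons excluded (one node is not a branch)."""
    sizes = np.bincount(labels)
    sizes = sizes[sizes >= 2]
    return np.sort(sizes)[::-1]


def raw_branching_score(
    cm: ConsistencyMatrix, thresholds: Optional[np.ndarray] = None
) -> tuple[float, float, np.ndarray]:
    """Score one candidate node from its consistency matrix.

    For each ``p_cut`` in ``thresholds`` the single-linkage dendrogram on
    the dissimilarity ``1 - B`` is cut at height ``1 - p_cut``; with the
    induced cluster sizes ``N_1 >= N_2 >= N_3 >= ...`` (clusters of at
    least two nodes; a singleton is not a branch) the per-threshold branch
    total is ``sum_{s>=3} N_s`` and the raw score is its mean over
    thresholds. The reported ``best_pcut`` maximises ``N_3`` (ties: larger
    branch total, then lower p_cut) and the returned ``branches`` are the
    clusters there, labelled 0.. in order of first appearance over
    ``cm.others``.

    Returns ``(score, best_pcut, branches)``.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    m = cm.B.shape[0]
    if m < 3:
        return 0.0, float(thresholds[0]), np.zeros(m, dtype=int)
    branch_totals, all_labels = _cluster_sizes_over_thresholds(cm.B, thresholds)
    score = float(branch_totals.mean())
    best = None
    best_key = (-1.0, -1.0)
    for t_i, pcut in enumerate(thresholds):
        sizes = _branch_sizes(all_labels[t_i])
        n3 = float(sizes[2]) if len(sizes) > 2 else 0.0
        key = (n3, float(branch_totals[t_i]))
        if key > best_key:
            best_key = key
            best = t_i
    best_pcut = float(thresholds[best])
    branches = _canonical_labels(all_labels[best])
    return score, best_pcut, branches


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0.. in order of first appearance."""
    out = np.empty(len(labels), dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def score_all_nodes(
    ensemble: TreeEnsemble, thresholds: Optional[np.ndarray] = None
) -> BranchingResult:
    """Raw branching score for every node; branch point = argmax (lowest index on ties)."""
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    k = ensemble.k
    counts = _co_branch_counts(ensemble)
    raw = np.empty(k)
    per_node: list[tuple[float, np.ndarray]] = []
    for x in range(k):
        others = np.concatenate([np.arange(x), np.arange(x + 1, k)])
        b = counts[x][np.ix_(others, others)] / ensemble.n
        np.fill_diagonal(b, 1.0)
        cm = ConsistencyMatrix(node_x=x, others=others, B=b)
        score, best_pcut, branches = raw_branching_score(cm, thresholds)
        raw[x] = score
        per_node.append((best_pcut, branches))
    branch_node = int(np.argmax(raw))
    best_pcut, branches = per_node[branch_node]
    node_branches = np.full(k, BRANCH_POINT_LABEL, dtype=int)
    others = np.concatenate([np.arange(branch_node), np.arange(branch_node + 1, k)])
    node_branches[others] = branches
    cell_branches = node_branches[ensemble.nodes.assignment]
    return BranchingResult(
        raw_scores=raw,
        branch_node=branch_node,
        best_pcut=best_pcut,
        node_branches=node_branches,
        cell_branches=cell_branches,
        retained_indices=ensemble.nodes.retained_indices,
    )


def mean_tree_distance(ensemble: TreeEnsemble, branch_node: int) -> np.ndarray:
    """Per node, the mean over trees of the tree-path length from ``branch_node``."""
    k = ensemble.k
    total = np.zeros(k)
    for tree in ensemble.trees:
        adj = tree.adjacency()
        dist = np.full(k, -1.0)
        dist[branch_node] = 0.0
        stack = [branch_node]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + w
                    stack.append(v)
        total += dist
    return total / ensemble.n


def marker_anova(
    values: np.ndarray,
    cell_branches: np.ndarray,
    species_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One-way ANOVA of each species across branches, Bonferroni-corrected.

    Cells labelled as the branch point (label ``BRANCH_POINT_LABEL``) are
    excluded; branches with fewer than 2 cells are dropped with a warning.
    Returns a DataFrame sorted by ascending corrected p-value.
    """
    values = np.asarray(values, dtype=float)
    cell_branches = np.asarray(cell_branches)
    mask = cell_branches != BRANCH_POINT_LABEL
    groups_all = np.unique(cell_branches[mask])
    groups = []
    for g in groups_all:
        members = values[cell_branches == g]
        if len(members) < 2:
            warnings.warn(f"branch {g} has fewer than 2 cells; excluded from ANOVA")
            continue
        groups.append(members)
    if len(groups) < 2:
        raise ValueError("need at least 2 branches with >= 2 cells each")
    d = values.shape[1]
    if species_names is None:
        species_names = [f"species_{j}" for j in range(d)]
    stats, ps = f_oneway(*groups, axis=0)
    p_bonf = np.minimum(np.asarray(ps) * d, 1.0)
    out = pd.DataFrame(
        {"species": list(species_names), "F": stats, "p": ps, "p_bonferroni": p_bonf}
    )
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def normalized_mutual_information(
    labels_a: Sequence, labels_b: Sequence, exclude: Sequence = ()
) -> float:
    """NMI = 2 I(A;B) / (H(A) + H(B)), with missing labels dropped first.

    Labels listed in ``exclude`` (plus None/NaN) are removed from both
    vectors before computing; defined as 0 when both partitions are
    constant (zero total entropy).
    """
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    drop = set(exclude)

    def _bad(x) -> bool:
        return x is None or x in drop or (isinstance(x, float) and np.isnan(x))

    mask = np.array([not (_bad(x) or _bad(y)) for x, y in zip(a, b)])
    a, b = a[mask], b[mask]
    if len(a) == 0:
        raise ValueError("no labelled cells remain after exclusion")
    _, ai = np.unique(a.astype(str), return_inverse=True)
    _, bi = np.unique(b.astype(str), return_inverse=True)
    n = len(ai)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= n
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    ha = -np.sum(pa[pa > 0] * np.log(pa[pa > 0]))
    hb = -np.sum(pb[pb > 0] * np.log(pb[pb > 0]))
    if ha + hb == 0:
        return 0.0
    nz = joint > 0
    mi = np.sum(joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz]))
    return float(2.0 * mi / (ha + hb))
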