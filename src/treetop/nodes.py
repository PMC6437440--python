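"""Reference-node selection and Voronoi partitioning.

``k`` reference cells are chosen to be evenly spread through the
(density-downsampled) data using the k-means++ seeding rule, then every
retained cell is assigned to its nearest node, partitioning the dataset
into a Voronoi tessellation. The seeding positions are used directly as
nodes; no Lloyd iterations follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import CellMatrix, DownsampleResult, distance_matrix

__all__ = ["ReferenceNodeSet", "select_reference_nodes", "assign_voronoi", "build_node_set"]


@dataclass
class ReferenceNodeSet:
    """k reference nodes plus the Voronoi assignment of retained cells.

    ``assignment`` maps positions in ``retained_indices`` (row indices into
    the full matrix, ascending) to node indices ``0..k-1``. Outliers carry
    no assignment.
    """

    node_cell_indices: np.ndarray  # (k,) row indices into the full matrix
    retained_indices: np.ndarray  # rows with an assignment
    assignment: np.ndarray  # (len(retained_indices),) values in 0..k-1

    @property
    def k(self) -> int:
        return len(self.node_cell_indices)

    @property
    def partition_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.k)

    def partition_members(self) -> list[np.ndarray]:
        """Row indices (full-matrix) of the cells in each Voronoi cell."""
        order = np.argsort(self.assignment, kind="stable")
        bounds = np.searchsorted(self.assignment[order], np.arange(self.k + 1))
        retained = self.retained_indices[order]
        return [retained[bounds[i] : bounds[i + 1]] for i in range(self.k)]


def select_reference_nodes(
    matrix: CellMatrix,
    kept_indices: np.ndarray,
    k: int,
    metric: str = "l1",
    seed: int = 0,
) -> np.ndarray:
    """k-means++ seeding over the kept cells.

    The first node is uniform at random; each subsequent node is sampled
    with probability proportional to squared distance (in the data metric)
    to its nearest already-chosen node. Returns full-matrix row indices.
    """
    kept_indices = np.asarray(kept_indices)
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(kept_indices):
        raise ValueError(
            f"k={k} exceeds the {len(kept_indices)} available cells; "
            "consider a smaller k for datasets with fewer cells"
        )
    rng = np.random.default_rng(seed)
    x = matrix.values[kept_indices]
    chosen = np.empty(k, dtype=int)
    chosen[0] = rng.integers(len(kept_indices))
    closest_sq = distance_matrix(x, x[chosen[0]][None, :], metric=metric)[:, 0] ** 2
    for j in range(1, k):
        total = closest_sq.sum()
        if total <= 0:
            # all remaining cells coincide with a chosen node: pick any unchosen
            remaining = np.setdiff1d(np.arange(len(kept_indices)), chosen[:j])
            chosen[j] = rng.choice(remaining)
        else:
            chosen[j] = rng.choice(len(kept_indices), p=closest_sq / total)
        d_new = distance_matrix(x, x[chosen[j]][None, :], metric=metric)[:, 0] ** 2
        np.minimum(closest_sq, d_new, out=closest_sq)
    return kept_indices[chosen]


def assign_voronoi(
    matrix: CellMatrix,
    node_cell_indices: np.ndarray,
    retained_indices: np.ndarray,
    metric: str = "l1",
    chunk: int = 4096,
) -> np.ndarray:
    """Nearest-node index for every retained cell; ties break to the lowest node."""
    node_x = matrix.values[np.asarray(node_cell_indices)]
    retained_indices = np.asarray(retained_indices)
    out = np.empty(len(retained_indices), dtype=int)
    for start in range(0, len(retained_indices), chunk):
        rows = retained_indices[start : start + chunk]
        d = distance_matrix(matrix.values[rows], node_x, metric=metric)
        out[start : start + len(rows)] = np.argmin(d, axis=1)
    return out


def build_node_set(
    matrix: CellMatrix,
    downsample: DownsampleResult,
    k: int,
    metric: str = "l1",
    seed: int = 0,
) -> ReferenceNodeSet:
    """Select nodes from kept cells, then assign kept + downsampled cells."""
    node_idx = select_reference_nodes(matrix, downsample.kept, k, metric=metric, seed=seed)
    retained = downsample.retained
    assignment = assign_voronoi(matrix, node_idx, retained, metric=metric)
    ns = ReferenceNodeSet(
        node_cell_indices=node_idx, retained_indices=retained, assignment=assignment
    )
    if (ns.partition_sizes < 1).any():
        raise RuntimeError("empty Voronoi partition; this violates node-set invariants")
    return ns
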