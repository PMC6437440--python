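"""Force-directed 2-D embedding of the pruned union graph, with overlays."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .ensemble import UnionGraph
from .nodes import ReferenceNodeSet
from .scoring import BRANCH_POINT_LABEL

__all__ = ["LayoutResult", "force_layout", "overlay"]


@dataclass
class LayoutResult:
    """2-D coordinates for reference nodes and (jittered) retained cells."""

    node_coordinates: np.ndarray  # (k, 2)
    cell_coordinates: np.ndarray  # (n_retained, 2)
    retained_indices: np.ndarray
    edges: list[tuple[int, int, float, float]]  # drawn edges (i, j, freq, mean_dist)


def force_layout(
    graph: UnionGraph,
    nodes: Optional[ReferenceNodeSet] = None,
    seed: int = 0,
    jitter_frac: float = 0.02,
) -> LayoutResult:
    """Spring-energy layout with target edge lengths = mean tree distances.

    Uses Kamada-Kawai minimisation (deterministic given the graph); cells
    inherit their node's position plus isotropic Gaussian jitter with SD
    ``jitter_frac`` of the layout diameter, seeded.
    """
    g = nx.Graph()
    g.add_nodes_from(range(graph.k))
    for i, j, freq, mean_dist in graph.edges:
        g.add_edge(i, j, weight=float(mean_dist), frequency=float(freq))
    if not nx.is_connected(g):
        raise ValueError("layout requires a connected (pruned) union graph")
    pos = nx.kamada_kawai_layout(g, weight="weight")
    coords = np.array([pos[i] for i in range(graph.k)])
    # networkx rescales to a unit box; restore absolute edge lengths with the
    # least-squares global scale against the target (mean tree) distances
    actual = np.array([np.linalg.norm(coords[i] - coords[j]) for i, j, _, _ in graph.edges])
    target = np.array([t for _, _, _, t in graph.edges])
    if (actual**2).sum() > 0:
        coords = coords * float((target * actual).sum() / (actual**2).sum())
    if not np.isfinite(coords).all():
        raise RuntimeError("layout produced non-finite coordinates")
    if nodes is None:
        cell_coords = coords.copy()
        retained = np.arange(graph.k)
    else:
        rng = np.random.default_rng(seed)
        span = coords.max(axis=0) - coords.min(axis=0)
        diameter = float(np.linalg.norm(span)) or 1.0
        cell_coords = coords[nodes.assignment] + rng.normal(
            scale=jitter_frac * diameter, size=(len(nodes.assignment), 2)
        )
        retained = nodes.retained_indices
    return LayoutResult(
        node_coordinates=coords,
        cell_coordinates=cell_coords,
        retained_indices=retained,
        edges=list(graph.edges),
    )


def overlay(
    layout: LayoutResult,
    values: Optional[Sequence] = None,
    labels: Optional[Sequence] = None,
    path: str = "treetop_layout.png",
    title: str = "",
    point_size: float = 4.0,
):
    """Scatter the layout coloured by a per-cell value or branch label.

    With ``labels``, each branch gets a legend entry and cells labelled as
    the branch point (label ``-1`` or ``"branch_point"``) are drawn black.
    Writes the figure to ``path`` and returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    n = len(layout.cell_coordinates)
    if values is not None and len(values) != n:
        raise ValueError("values must align with retained cells")
    if labels is not None and len(labels) != n:
        raise ValueError("labels must align with retained cells")
    fig, ax = plt.subplots(figsize=(6, 5))
    xy = layout.cell_coordinates
    if labels is not None:
        labels = np.asarray(labels)
        is_bp = (labels == BRANCH_POINT_LABEL) | (labels.astype(str) == "branch_point")
        for lab in sorted({str(v) for v in labels[~is_bp]}):
            sel = (~is_bp) & (labels.astype(str) == lab)
            ax.scatter(xy[sel, 0], xy[sel, 1], s=point_size, label=f"branch {lab}")
        if is_bp.any():
            ax.scatter(xy[is_bp, 0], xy[is_bp, 1], s=point_size, c="black", label="branch point")
        ax.legend(markerscale=3, fontsize=8)
    elif values is not None:
        sc = ax.scatter(xy[:, 0], xy[:, 1], s=point_size, c=np.asarray(values, dtype=float))
        fig.colorbar(sc, ax=ax)
    else:
        ax.scatter(xy[:, 0], xy[:, 1], s=point_size, c="grey")
    for i, j, _, _ in layout.edges:
        a, b = layout.node_coordinates[i], layout.node_coordinates[j]
        ax.plot([a[0], b[0]], [a[1], b[1]], color="0.6", lw=0.5, zorder=0)
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return fig
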