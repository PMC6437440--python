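"""Full pipeline orchestration and recursive branch-hierarchy reconstruction.

``run_treetop`` chains preprocessing, node selection, tree-ensemble
sampling, branch scoring and reference normalisation into one seeded run.
``recursive_treetop`` applies the same run to each identified branch,
descending while the relative branching score exceeds 1 and branches stay
large enough, which reconstructs multi-level hierarchies such as
hematopoietic differentiation trees.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from . import reference as ref
from .ensemble import build_ensemble
from .nodes import build_node_set
from .preprocess import (
    CellMatrix,
    arcsinh_transform,
    auto_sigma,
    compute_density,
    density_downsample,
    diffusion_map,
    elbow_components,
)
from .scoring import DEFAULT_THRESHOLDS, BranchingResult, score_all_nodes

__all__ = ["TreeTopConfig", "BranchHierarchy", "run_treetop", "recursive_treetop"]

#: the hard floor on dataset size; too few cells make branch geometry unidentifiable
MIN_CELLS_FLOOR = 1000


@dataclass
class TreeTopConfig:
    """All tunable parameters of a run; every random choice flows from ``seed``.

    ``cofactor=None`` means the input is already variance-stabilised;
    ``sigma=None`` picks the density radius automatically as the
    ``sigma_percentile``-th percentile of pairwise distances;
    ``n_components=None`` skips diffusion-map reduction, ``"auto"`` selects
    the component count by the eigen-gap elbow.
    """

    cofactor: Optional[float] = None
    metric: str = "l1"
    sigma: Optional[float] = None
    sigma_percentile: float = 5.0
    outlier_percentile: float = 1.0
    target_percentile: float = 5.0
    k: int = 200
    n_trees: int = 1000
    n_components: Union[int, str, None] = None
    thresholds: np.ndarray = field(default_factory=lambda: DEFAULT_THRESHOLDS.copy())
    reference_table: Union[str, "ref.ReferenceTable", None] = None
    seed: int = 0
    min_cells: int = MIN_CELLS_FLOOR
    allow_small: bool = False
    recurse_threshold: float = 1.0
    max_depth: int = 3

    def __post_init__(self) -> None:
        if self.min_cells < MIN_CELLS_FLOOR and not self.allow_small:
            raise ValueError(
                f"min_cells below {MIN_CELLS_FLOOR} requires allow_small=True; "
                "branch analysis is unreliable on small datasets"
            )

    def replace(self, **changes) -> "TreeTopConfig":
        return dataclasses.replace(self, **changes)

    def resolve_reference(self) -> "ref.ReferenceTable":
        if isinstance(self.reference_table, ref.ReferenceTable):
            return self.reference_table
        if self.reference_table is None:
            return ref.ReferenceTable.shipped()
        return ref.ReferenceTable.load(self.reference_table)


@dataclass
class BranchHierarchy:
    """A node of the recursive branching tree."""

    result: BranchingResult
    depth: int
    n_cells: int
    children: dict[int, "BranchHierarchy"] = field(default_factory=dict)
    leaf_reasons: dict[int, str] = field(default_factory=dict)  # branch label -> stop reason

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def max_depth(self) -> int:
        if not self.children:
            return self.depth
        return max(child.max_depth for child in self.children.values())

    def to_dict(self) -> dict:
        """JSON-serialisable summary of the hierarchy."""
        out = {
            "depth": self.depth,
            "n_cells": self.n_cells,
            "branch_node": int(self.result.branch_node),
            "relative_score": self.result.relative_score,
            "n_branches": int(self.result.n_branches),
            "branches": {},
        }
        for label in range(self.result.n_branches):
            if label in self.children:
                out["branches"][str(label)] = self.to_dict_child(label)
            else:
                out["branches"][str(label)] = {
                    "leaf": True,
                    "reason": self.leaf_reasons.get(label, "no_branching"),
                }
        return out

    def to_dict_child(self, label: int) -> dict:
        return self.children[label].to_dict()


def _preprocess(matrix: CellMatrix, config: TreeTopConfig) -> CellMatrix:
    values = matrix.values
    if config.cofactor is not None:
        values = arcsinh_transform(values, config.cofactor)
    work = CellMatrix(
        values=values,
        species_names=list(matrix.species_names),
        cell_ids=list(matrix.cell_ids),
        labels=matrix.labels,
    )
    if config.n_components is not None:
        if config.n_components == "auto":
            probe = min(15, work.n_cells - 1)
            _, evals = diffusion_map(work, n_components=probe, metric=config.metric)
            n_comp = elbow_components(evals)
        else:
            n_comp = int(config.n_components)
        embedding, _ = diffusion_map(work, n_components=n_comp, metric=config.metric)
        work = CellMatrix(
            values=embedding,
            species_names=[f"DC{j + 1}" for j in range(embedding.shape[1])],
            cell_ids=list(work.cell_ids),
            labels=work.labels,
        )
    return work


def run_treetop(
    matrix: CellMatrix,
    config: Optional[TreeTopConfig] = None,
    with_reference: bool = True,
) -> BranchingResult:
    """One full branch-point analysis of ``matrix``.

    Steps: optional arcsinh transform and diffusion-map reduction; density
    estimation and SPADE-style downsampling; k-means++ reference-node
    selection and Voronoi assignment; MST-ensemble sampling; branching
    scores for every node; and (unless ``with_reference=False``) lookup of
    the matched reference distribution to report the relative branching
    score. Refuses datasets with fewer than ``config.min_cells`` cells.
    """
    if config is None:
        config = TreeTopConfig()
    if matrix.n_cells < config.min_cells:
        raise ValueError(
            f"dataset has {matrix.n_cells} cells, fewer than the required "
            f"{config.min_cells}; branch analysis needs at least that many"
        )
    work = _preprocess(matrix, config)
    sigma = config.sigma
    if sigma is None:
        sigma = auto_sigma(
            work, metric=config.metric, percentile=config.sigma_percentile,
            seed=config.seed,
        )
    density = compute_density(work, sigma=sigma, metric=config.metric)
    ds = density_downsample(
        work,
        density,
        outlier_percentile=config.outlier_percentile,
        target_percentile=config.target_percentile,
        seed=config.seed + 11,
    )
    nodes = build_node_set(work, ds, k=config.k, metric=config.metric, seed=config.seed + 23)
    ensemble = build_ensemble(
        work, nodes, n_trees=config.n_trees, metric=config.metric, seed=config.seed + 1000
    )
    result = score_all_nodes(ensemble, thresholds=config.thresholds)
    result.extras["ensemble"] = ensemble
    result.extras["downsample"] = ds
    result.extras["sigma"] = float(sigma)
    result.extras["matrix"] = work
    if with_reference:
        table = config.resolve_reference()
        cell = table.lookup(n_obs=matrix.n_cells, d=work.n_species, k=config.k)
        result.b_ref = cell.b_ref
        result.reference_params = (
            cell.params.n_obs,
            cell.params.d,
            cell.params.k,
            cell.params.rho,
        )
        result.relative_score = ref.relative_score(result.b_max, cell.b_ref)
    return result


def recursive_treetop(
    matrix: CellMatrix, config: Optional[TreeTopConfig] = None, _depth: int = 0
) -> BranchHierarchy:
    """Depth-first recursive branch detection.

    Runs the full pipeline; if the relative branching score exceeds
    ``config.recurse_threshold``, each identified branch's cells form a new
    dataset (the branch-point cells belong to no branch and are not passed
    down) which is analysed afresh — its own sigma, nodes and reference
    lookup. A branch becomes a leaf when its parent shows no branching,
    when it has fewer than ``min_cells`` cells, or at ``max_depth``.
    """
    if config is None:
        config = TreeTopConfig()
    if _depth == 0 and config.cofactor is not None:
        # transform once at the root; children inherit transformed values
        matrix = CellMatrix(
            values=arcsinh_transform(matrix.values, config.cofactor),
            species_names=list(matrix.species_names),
            cell_ids=list(matrix.cell_ids),
            labels=matrix.labels,
        )
        config = config.replace(cofactor=None)
    result = run_treetop(matrix, config)
    node = BranchHierarchy(result=result, depth=_depth, n_cells=matrix.n_cells)
    score = result.relative_score
    if score is None or score <= config.recurse_threshold:
        return node
    if _depth + 1 > config.max_depth:
        for label in range(result.n_branches):
            node.leaf_reasons[label] = "max_depth"
        return node
    for label in range(result.n_branches):
        rows = result.retained_indices[result.cell_branches == label]
        if len(rows) < config.min_cells:
            node.leaf_reasons[label] = "min_cells"
            continue
        sub = matrix.subset(rows)
        child_seed = (config.seed + 100003 * (label + 1)) % (2**31)
        child_cfg = config.replace(seed=child_seed)
        node.children[label] = recursive_treetop(sub, child_cfg, _depth=_depth + 1)
    return node
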