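"""Reference score distributions from non-branching synthetic data.

Raw branching scores have no absolute scale: even data sampled from a
topology with no branch point produces positive scores, and the magnitude
depends on the number of cells, the dimensionality and the number of
reference nodes. Scores are therefore normalised against the distribution
of *maximum* raw scores obtained by running the full pipeline on synthetic
non-branching datasets matched in (n_obs, d, k). Among simple connected
non-branching manifolds, filled 2-D triangles (noise-free, embedded in d
dimensions) give the highest raw scores, so they form a conservative
null: the relative branching score is b_max / b_ref where b_ref is the
95th percentile of the triangle score distribution, and values above 1
indicate branching evidence beyond anything a non-branching topology
produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import CellMatrix

__all__ = [
    "GRID_N_OBS",
    "GRID_D",
    "GRID_K",
    "GRID_RHO",
    "ReferenceParams",
    "ReferenceScoreDistribution",
    "ReferenceTable",
    "reference_grid",
    "generate_triangle_dataset",
    "build_reference_distribution",
    "lookup_reference",
    "relative_score",
]

#: the precomputed-lookup parameter grid (240 combinations)
GRID_N_OBS = tuple(range(10_000, 100_001, 10_000))
GRID_D = (5, 10, 15, 20, 25, 30)
GRID_K = (50, 100, 150, 200)
GRID_RHO = (0.0,)


@dataclass(frozen=True)
class ReferenceParams:
    """One cell of the reference grid: dataset size, dimensionality, node count, noise SD."""

    n_obs: int
    d: int
    k: int
    rho: float = 0.0


def reference_grid() -> list[ReferenceParams]:
    """All grid combinations used for precomputed reference distributions."""
    return [
        ReferenceParams(n_obs=n, d=d, k=k, rho=r)
        for n in GRID_N_OBS
        for d in GRID_D
        for k in GRID_K
        for r in GRID_RHO
    ]


@dataclass
class ReferenceScoreDistribution:
    """Maximum raw scores from replicate non-branching runs at fixed params."""

    params: ReferenceParams
    max_scores: np.ndarray
    seed: int = 0
    n_trees: int = 0  # ensemble size the replicates were scored with

    def __post_init__(self) -> None:
        self.max_scores = np.asarray(self.max_scores, dtype=float)
        if len(self.max_scores) < 1:
            raise ValueError("need at least one replicate score")

    @property
    def n_reps(self) -> int:
        return len(self.max_scores)

    @property
    def b_ref(self) -> float:
        """95th percentile of the max scores (linear interpolation between order stats)."""
        return float(np.percentile(self.max_scores, 95))


# equilateral triangle, side 1, centred at the origin
_TRI_VERTICES = (1.0 / np.sqrt(3.0)) * np.array(
    [
        [np.cos(np.pi / 2), np.sin(np.pi / 2)],
        [np.cos(np.pi / 2 + 2 * np.pi / 3), np.sin(np.pi / 2 + 2 * np.pi / 3)],
        [np.cos(np.pi / 2 + 4 * np.pi / 3), np.sin(np.pi / 2 + 4 * np.pi / 3)],
    ]
)


def generate_triangle_dataset(params: ReferenceParams, seed: int = 0) -> CellMatrix:
    """Uniform samples on a filled 2-D triangle embedded in d dimensions.

    The triangle (equilateral, side 1, centred at the origin) occupies the
    first two coordinates; the remaining d-2 coordinates are zero. Isotropic
    Gaussian noise of SD ``params.rho`` is added in all d dimensions.
    """
    if params.d < 2:
        raise ValueError("need d >= 2 to embed a 2-D manifold")
    rng = np.random.default_rng(seed)
    u = rng.random(params.n_obs)
    v = rng.random(params.n_obs)
    s = np.sqrt(u)
    bary = np.stack([1.0 - s, s * (1.0 - v), s * v], axis=1)  # uniform barycentric
    plane = bary @ _TRI_VERTICES
    x = np.zeros((params.n_obs, params.d))
    x[:, :2] = plane
    if params.rho > 0:
        x += rng.normal(scale=params.rho, size=x.shape)
    return CellMatrix(values=x, species_names=[f"dim_{j}" for j in range(params.d)])


def build_reference_distribution(
    params: ReferenceParams,
    n_reps: int = 100,
    seed: int = 0,
    config=None,
    progress: bool = False,
) -> ReferenceScoreDistribution:
    """Run the full pipeline on ``n_reps`` triangle datasets; record max raw scores.

    ``config`` is a :class:`~treetop.recursion.TreeTopConfig`; its ``k`` is
    overridden by ``params.k``. Replicate r uses seed ``seed + r`` for both
    data generation and the pipeline.
    """
    from .recursion import TreeTopConfig, run_treetop  # deferred: avoids import cycle

    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if config is None:
        config = TreeTopConfig()
    scores = np.empty(n_reps)
    for r in range(n_reps):
        rep_seed = seed + r
        data = generate_triangle_dataset(params, seed=rep_seed)
        cfg = config.replace(k=params.k, seed=rep_seed, cofactor=None)
        result = run_treetop(data, cfg, with_reference=False)
        scores[r] = result.b_max
        if progress:
            print(f"  replicate {r + 1}/{n_reps}: max raw score {scores[r]:.3f}", flush=True)
    return ReferenceScoreDistribution(
        params=params, max_scores=scores, seed=seed, n_trees=config.n_trees
    )


@dataclass
class ReferenceTable:
    """A set of reference score distributions with nearest-cell lookup."""

    cells: list[ReferenceScoreDistribution] = field(default_factory=list)

    def add(self, dist: ReferenceScoreDistribution) -> None:
        self.cells.append(dist)

    def lookup(self, n_obs: int, d: int, k: int) -> ReferenceScoreDistribution:
        return lookup_reference(self.cells, n_obs, d, k)

    # --- persistence: an index CSV plus one max-scores CSV per grid cell ---

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for cell in self.cells:
            p = cell.params
            fname = f"ref_n{p.n_obs}_d{p.d}_k{p.k}_rho{p.rho:g}.csv"
            pd.DataFrame({"max_score": cell.max_scores}).to_csv(
                directory / fname, index=False, float_format="%.10g"
            )
            rows.append(
                {
                    "n_obs": p.n_obs,
                    "d": p.d,
                    "k": p.k,
                    "rho": p.rho,
                    "n_reps": cell.n_reps,
                    "seed": cell.seed,
                    "n_trees": cell.n_trees,
                    "b_ref": cell.b_ref,
                    "filename": fname,
                }
            )
        pd.DataFrame(rows).to_csv(directory / "index.csv", index=False, float_format="%.10g")

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceTable":
        directory = Path(directory)
        index = pd.read_csv(directory / "index.csv")
        table = cls()
        for _, row in index.iterrows():
            scores = pd.read_csv(directory / row["filename"])["max_score"].to_numpy()
            table.add(
                ReferenceScoreDistribution(
                    params=ReferenceParams(
                        n_obs=int(row["n_obs"]),
                        d=int(row["d"]),
                        k=int(row["k"]),
                        rho=float(row["rho"]),
                    ),
                    max_scores=scores,
                    seed=int(row["seed"]),
                    n_trees=int(row["n_trees"]),
                )
            )
        return table

    @classmethod
    def shipped(cls) -> "ReferenceTable":
        """The reduced-grid table distributed with the package."""
        from importlib.resources import files

        return cls.load(Path(str(files("treetop.data") / "reference")))


# normalisation spans for nearest-cell lookup, from the full grid extents
_SPANS = (
    GRID_N_OBS[-1] - GRID_N_OBS[0],
    GRID_D[-1] - GRID_D[0],
    GRID_K[-1] - GRID_K[0],
)


def lookup_reference(
    cells: list[ReferenceScoreDistribution], n_obs: int, d: int, k: int
) -> ReferenceScoreDistribution:
    """Closest most conservative grid cell for the query parameters.

    Distance is Euclidean on (n_obs, d, k) with each axis normalised by the
    full grid span; ties go to the cell with the larger ``b_ref`` (more
    conservative). Queries outside the grid hull raise a warning and use
    the nearest edge cell.
    """
    if not cells:
        raise ValueError("reference table is empty")
    if not (GRID_N_OBS[0] <= n_obs <= GRID_N_OBS[-1]) or not (
        GRID_D[0] <= d <= GRID_D[-1]
    ) or not (GRID_K[0] <= k <= GRID_K[-1]):
        warnings.warn(
            f"query (n_obs={n_obs}, d={d}, k={k}) lies outside the reference grid; "
            "using the nearest edge cell"
        )
    best: Optional[ReferenceScoreDistribution] = None
    best_key: Optional[tuple[float, float]] = None
    for cell in cells:
        p = cell.params
        dist = np.sqrt(
            ((n_obs - p.n_obs) / _SPANS[0]) ** 2
            + ((d - p.d) / _SPANS[1]) ** 2
            + ((k - p.k) / _SPANS[2]) ** 2
        )
        key = (dist, -cell.b_ref)
        if best_key is None or key < best_key:
            best_key = key
            best = cell
    return best


def relative_score(b_max: float, b_ref: float) -> float:
    """Relative branching score b_max / b_ref; > 1 indicates branching evidence."""
    if b_ref <= 0:
        raise ValueError("degenerate reference distribution: b_ref must be positive")
    return float(b_max) / float(b_ref)
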