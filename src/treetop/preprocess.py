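"""Preprocessing of single-cell abundance matrices.

Covers the steps applied before any branch analysis: variance-stabilising
arcsinh transformation of cytometry counts, distance metrics (L1 by
default), kernel-density estimation by neighbour counting within a radius
``sigma``, SPADE-style density-dependent downsampling with outlier removal,
and diffusion-map dimensionality reduction with an elbow heuristic for
choosing the number of components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.neighbors import BallTree

__all__ = [
    "CellMatrix",
    "DensityProfile",
    "DownsampleResult",
    "METRICS",
    "arcsinh_transform",
    "pairwise_distance",
    "distance_matrix",
    "compute_density",
    "suggest_sigma",
    "density_downsample",
    "diffusion_map",
    "elbow_components",
]

#: distance metrics supported throughout the pipeline
METRICS = ("l1", "l2", "angle")

_CDIST_NAME = {"l1": "cityblock", "l2": "euclidean"}


@dataclass
class CellMatrix:
    """A cells x species abundance table with per-cell metadata.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_cells, d)``; unitless after transform.
    species_names
        One name per column.
    cell_ids
        One identifier per row; defaults to 0-based row indices.
    labels
        Optional per-cell category (gates or ground-truth branches).
    """

    values: np.ndarray
    species_names: list[str] = field(default_factory=list)
    cell_ids: list = field(default_factory=list)
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (cells x species)")
        if not np.isfinite(self.values).all():
            raise ValueError("abundance matrix contains missing or non-finite values")
        n, d = self.values.shape
        if not self.species_names:
            self.species_names = [f"species_{j}" for j in range(d)]
        if len(self.species_names) != d:
            raise ValueError("species_names length does not match number of columns")
        if not len(self.cell_ids):
            self.cell_ids = list(range(n))
        if len(self.cell_ids) != n:
            raise ValueError("cell_ids length does not match number of rows")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length does not match number of rows")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_species(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: np.ndarray) -> "CellMatrix":
        """Row subset preserving identifiers and labels."""
        indices = np.asarray(indices)
        return CellMatrix(
            values=self.values[indices],
            species_names=list(self.species_names),
            cell_ids=[self.cell_ids[i] for i in indices],
            labels=None if self.labels is None else self.labels[indices],
        )


@dataclass
class DensityProfile:
    """Neighbour count within radius ``sigma`` for every cell."""

    density: np.ndarray  # positive integers, self included
    sigma: float

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=int)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if (self.density < 1).any():
            raise ValueError("every cell is within sigma of itself; density >= 1")


@dataclass
class DownsampleResult:
    """Disjoint partition of cell indices after density downsampling.

    ``downsampled`` cells are removed for reference-node selection but
    re-included for the Voronoi tessellation; ``outliers`` are permanently
    excluded.
    """

    kept: np.ndarray
    downsampled: np.ndarray
    outliers: np.ndarray

    @property
    def retained(self) -> np.ndarray:
        """Kept plus downsampled cells, in ascending index order."""
        return np.sort(np.concatenate([self.kept, self.downsampled]))


def arcsinh_transform(values: np.ndarray, cofactor: float = 5.0) -> np.ndarray:
    """Elementwise ``asinh(x / cofactor)``.

    Cofactor 5 is the convention for mass cytometry; flow cytometry
    typically uses ~150 depending on the fluorescent tag.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor)


def _angle_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(a, axis=-1)
    nb = np.linalg.norm(b, axis=-1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("angle distance is undefined for zero vectors")
    cos = (a * b).sum(axis=-1) / (na * nb)
    return np.arccos(np.clip(cos, -1.0, 1.0))


def pairwise_distance(a: Sequence[float], b: Sequence[float], metric: str = "l1") -> float:
    """Distance between two vectors under ``l1``, ``l2`` or ``angle``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if metric == "l1":
        return float(np.abs(a - b).sum())
    if metric == "l2":
        return float(np.sqrt(((a - b) ** 2).sum()))
    if metric == "angle":
        return float(_angle_distance(a, b))
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def distance_matrix(a: np.ndarray, b: np.ndarray, metric: str = "l1") -> np.ndarray:
    """All pairwise distances between rows of ``a`` and rows of ``b``."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if metric in _CDIST_NAME:
        return cdist(a, b, metric=_CDIST_NAME[metric])
    if metric == "angle":
        if np.any(np.linalg.norm(a, axis=1) == 0) or np.any(np.linalg.norm(b, axis=1) == 0):
            raise ValueError("angle distance is undefined for zero vectors")
        return np.arccos(np.clip(1.0 - cdist(a, b, metric="cosine"), -1.0, 1.0))
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def suggest_sigma(
    matrix: CellMatrix,
    metric: str = "l1",
    percentiles: Sequence[float] = (1, 5, 10, 25, 50),
    max_sample: int = 2000,
    seed: int = 0,
) -> dict[float, float]:
    """Percentiles of the pairwise-distance distribution, to guide sigma.

    A subsample of at most ``max_sample`` cells is used, so the result is a
    seeded estimate on large inputs.
    """
    rng = np.random.default_rng(seed)
    n = matrix.n_cells
    idx = rng.choice(n, size=min(n, max_sample), replace=False) if n > max_sample else np.arange(n)
    x = matrix.values[idx]
    if metric in _CDIST_NAME:
        d = pdist(x, metric=_CDIST_NAME[metric])
    else:
        d = distance_matrix(x, x, metric=metric)[np.triu_indices(len(x), k=1)]
    return {float(p): float(np.percentile(d, p)) for p in percentiles}


def auto_sigma(
    matrix: CellMatrix, metric: str = "l1", percentile: float = 5.0, seed: int = 0
) -> float:
    """Density radius from the pairwise-distance distribution.

    Uses the requested percentile; if that is zero (heavily duplicated
    data), falls back to the smallest positive distance in the subsample.
    """
    rng = np.random.default_rng(seed)
    n = matrix.n_cells
    idx = rng.choice(n, size=min(n, 2000), replace=False) if n > 2000 else np.arange(n)
    x = matrix.values[idx]
    if metric in _CDIST_NAME:
        d = pdist(x, metric=_CDIST_NAME[metric])
    else:
        d = distance_matrix(x, x, metric=metric)[np.triu_indices(len(x), k=1)]
    sigma = float(np.percentile(d, percentile))
    if sigma <= 0:
        positive = d[d > 0]
        if len(positive) == 0:
            raise ValueError("all cells coincide; cannot choose a density radius")
        sigma = float(positive.min())
    return sigma


def compute_density(matrix: CellMatrix, sigma: float, metric: str = "l1") -> DensityProfile:
    """Count neighbours within radius ``sigma`` (self included) per cell."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if metric in _CDIST_NAME:
        tree = BallTree(matrix.values, metric=_CDIST_NAME[metric])
        counts = tree.query_radius(matrix.values, r=sigma, count_only=True)
    else:
        d = distance_matrix(matrix.values, matrix.values, metric=metric)
        counts = (d <= sigma).sum(axis=1)
    return DensityProfile(density=np.asarray(counts, dtype=int), sigma=float(sigma))


def density_downsample(
    matrix: CellMatrix,
    density: DensityProfile,
    outlier_percentile: float = 1.0,
    target_percentile: float = 5.0,
    seed: int = 0,
) -> DownsampleResult:
    """SPADE-style density-dependent downsampling.

    Cells with local density below the ``outlier_percentile`` density are
    marked outliers; cells above the ``target_percentile`` density ``TD``
    are kept with probability ``TD / density``; everything in between is
    kept. If all densities are equal (no density structure) nothing is
    removed.
    """
    if not (0 <= outlier_percentile < target_percentile <= 100):
        raise ValueError("need 0 <= outlier_percentile < target_percentile <= 100")
    dens = density.density.astype(float)
    if len(dens) != matrix.n_cells:
        raise ValueError("density profile does not match matrix")
    rng = np.random.default_rng(seed)
    all_idx = np.arange(matrix.n_cells)
    if np.all(dens == dens[0]):
        return DownsampleResult(kept=all_idx, downsampled=all_idx[:0], outliers=all_idx[:0])
    od = np.percentile(dens, outlier_percentile)
    td = np.percentile(dens, target_percentile)
    outlier_mask = dens < od
    keep_prob = np.ones_like(dens)
    above = dens > td
    keep_prob[above] = td / dens[above]
    drop_mask = (~outlier_mask) & (rng.random(len(dens)) > keep_prob)
    kept_mask = ~outlier_mask & ~drop_mask
    return DownsampleResult(
        kept=all_idx[kept_mask],
        downsampled=all_idx[drop_mask],
        outliers=all_idx[outlier_mask],
    )


def diffusion_map(
    matrix: CellMatrix,
    n_components: int = 10,
    kernel_sigma: Optional[float] = None,
    metric: str = "l2",
) -> tuple[np.ndarray, np.ndarray]:
    """Diffusion-map embedding (Coifman construction).

    Builds a Gaussian kernel ``W = exp(-d^2 / (2 sigma^2))``, row-normalises
    it into a Markov matrix and eigendecomposes; the trivial constant
    eigenvector (eigenvalue 1) is dropped. ``kernel_sigma`` defaults to the
    median pairwise distance.

    Returns
    -------
    embedding : (n_cells, n_components) array
        Diffusion components scaled by their eigenvalues, ordered by
        descending eigenvalue.
    eigenvalues : (n_components,) array, non-increasing.
    """
    n = matrix.n_cells
    if not 0 < n_components < n:
        raise ValueError("need 0 < n_components < n_cells")
    d = distance_matrix(matrix.values, matrix.values, metric=metric)
    if kernel_sigma is None:
        kernel_sigma = float(np.median(d[np.triu_indices(n, k=1)]))
    if kernel_sigma <= 0:
        raise ValueError("kernel_sigma must be positive")
    w = np.exp(-(d**2) / (2.0 * kernel_sigma**2))
    row = w.sum(axis=1)
    if np.any(w.sum(axis=1) - 1.0 <= 1e-12):  # only self-similarity
        warnings.warn("kernel graph is (nearly) disconnected; embedding may be degenerate")
    # symmetric conjugate of the Markov matrix shares its eigenvalues
    inv_sqrt = 1.0 / np.sqrt(row)
    a = w * np.outer(inv_sqrt, inv_sqrt)
    evals, evecs = np.linalg.eigh(a)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    # right eigenvectors of the Markov matrix
    psi = evecs[:, order] * inv_sqrt[:, None]
    # drop the trivial constant eigenvector at eigenvalue ~1
    evals_nt = evals[1 : n_components + 1]
    psi_nt = psi[:, 1 : n_components + 1]
    embedding = psi_nt * evals_nt[None, :]
    return embedding, evals_nt


def elbow_components(eigenvalues: Sequence[float]) -> int:
    """Number of components by the largest consecutive eigen-gap.

    Returns the index ``i`` (1-based count of components) maximising
    ``eigenvalues[i-1] - eigenvalues[i]``; ties break toward fewer
    components.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if len(ev) < 3:
        raise ValueError("need at least 3 eigenvalues for the elbow heuristic")
    gaps = ev[:-1] - ev[1:]
    return int(np.argmax(gaps)) + 1
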