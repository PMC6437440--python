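"""Synthetic single-cell data: toggle-switch hierarchies and simple geometries.

The branching positive control is a tree of stochastic binary
toggle-switches: each switch is a pair of mutually inhibiting proteins,
and whichever protein wins activates the next switch on its arm, so one
trajectory mimics the multi-step differentiation of a single cell.
Production follows Hill kinetics — activation from the upstream protein
and inhibition by the switch partner — and degradation is mass-action.
Trajectories are advanced by fixed-step tau-leaping (Poisson event counts
per reaction per step) from Poisson(lambda) initial counts, and snapshots
at random (trajectory, time) pairs yield a single-cell matrix with
ground-truth fate labels.

Simple geometric generators (path, star, circle, blob, triangle) supply
branching and non-branching controls of known topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import CellMatrix
from .reference import ReferenceParams, generate_triangle_dataset

__all__ = [
    "ToggleSwitchModel",
    "SimulationRun",
    "production_propensity",
    "degradation_propensity",
    "build_hierarchy_model",
    "tau_leap_simulate",
    "sample_cells_from_run",
    "generate_geometry",
]


@dataclass
class ToggleSwitchModel:
    """A binary tree of toggle switches.

    Species are indexed 0..n_species-1; ``upstream[i]`` is the activating
    protein of species i (-1 for the two root-switch proteins, which need
    no upstream activation) and ``partner[i]`` is the mutually inhibiting
    protein within the same switch. Rate parameters per species: ``alpha``
    (basal production, molecules/time), ``kappa_act``/``h_act``
    (activation dissociation constant and Hill coefficient),
    ``kappa_inh``/``h_inh`` (inhibition), ``delta`` (degradation rate,
    1/time).
    """

    upstream: np.ndarray
    partner: np.ndarray
    alpha: np.ndarray
    kappa_act: np.ndarray
    h_act: np.ndarray
    kappa_inh: np.ndarray
    h_inh: np.ndarray
    delta: np.ndarray
    depth: int = 1

    def __post_init__(self) -> None:
        n = len(self.upstream)
        for name in ("partner", "alpha", "kappa_act", "h_act", "kappa_inh", "h_inh", "delta"):
            arr = np.asarray(getattr(self, name), dtype=float if name != "partner" else int)
            if len(arr) != n:
                raise ValueError(f"{name} must have one entry per species")
            setattr(self, name, arr)
        self.upstream = np.asarray(self.upstream, dtype=int)
        for name in ("alpha", "kappa_act", "h_act", "kappa_inh", "h_inh", "delta"):
            if (getattr(self, name) <= 0).any():
                raise ValueError(f"{name} must be strictly positive")
        if (self.partner[self.partner] != np.arange(n)).any():
            raise ValueError("switch partners must be mutual")

    @property
    def n_species(self) -> int:
        return len(self.upstream)

    def species_names(self) -> list[str]:
        return [f"g{i}" for i in range(self.n_species)]


@dataclass
class SimulationRun:
    """Trajectories (n_traj, n_timepoints, n_species) of integer counts."""

    trajectories: np.ndarray
    time_grid: np.ndarray
    seed: int
    model: ToggleSwitchModel

    def __post_init__(self) -> None:
        if (self.trajectories < 0).any():
            raise ValueError("counts must be nonnegative")


def production_propensity(
    g_u: float | np.ndarray,
    g_s: float | np.ndarray,
    alpha: float,
    kappa_act: float,
    h_act: float,
    kappa_inh: float,
    h_inh: float,
) -> float | np.ndarray:
    """Hill production rate: activated from upstream, inhibited by the partner.

    ``alpha * g_u^h+ / (g_u^h+ + kappa+^h+) * kappa-^h- / (g_s^h- + kappa-^h-)``,
    bounded in [0, alpha]. Pass ``g_u=None`` for a root protein with no
    upstream regulator (the activation term is then 1).
    """
    inh = kappa_inh**h_inh / (np.asarray(g_s, dtype=float) ** h_inh + kappa_inh**h_inh)
    if g_u is None:
        return alpha * inh
    g_u = np.asarray(g_u, dtype=float)
    act = np.where(g_u > 0, g_u**h_act / (g_u**h_act + kappa_act**h_act), 0.0)
    return alpha * act * inh


def degradation_propensity(g: float | np.ndarray, delta: float) -> float | np.ndarray:
    """Mass-action degradation rate ``delta * g``."""
    return delta * np.asarray(g, dtype=float)


# Default kinetics: each switch's deterministic limit is bistable (winner
# ~ alpha/delta = 200, loser ~ 0) and commitment completes well within the
# default horizon t = 150. Two constants carry the hierarchy:
#   * kappa_act sits between the resting level and the winner's steady state,
#     so a downstream switch only activates AFTER its upstream protein has won
#     its own switch — commitment is sequential down the tree rather than a
#     one-shot fan into all terminal fates;
#   * kappa_inh is far below the Poisson(100) initial counts, so undecided
#     proteins decay over a long arc (100 -> ~10) before the race resolves,
#     giving each branch point a well-populated incoming trajectory segment
#     the way progenitor compartments precede fate splits in real data.
_DEFAULT_RATES = dict(alpha=40.0, kappa_act=150.0, h_act=4.0, kappa_inh=10.0, h_inh=4.0, delta=0.2)


def build_hierarchy_model(depth: int = 1, **rates) -> ToggleSwitchModel:
    """Complete binary tree of toggle switches with ``depth`` levels.

    Level 1 is the root switch (two proteins, no upstream activator); each
    protein at level l < depth activates a downstream switch of two
    proteins, giving ``2^(depth+1) - 2`` species in total. Keyword
    arguments override the default rate constants (scalar, applied to all
    species).
    """
    if depth < 1:
        raise ValueError("depth must be at least 1")
    params = {**_DEFAULT_RATES, **rates}
    # heap numbering: proteins occupy heap slots 2 .. 2^(depth+1)-1
    n = 2 ** (depth + 1) - 2
    heap = np.arange(2, n + 2)
    upstream = np.where(heap < 4, -1, heap // 2 - 2)
    partner = (heap ^ 1) - 2
    ones = np.ones(n)
    return ToggleSwitchModel(
        upstream=upstream,
        partner=partner,
        alpha=ones * params["alpha"],
        kappa_act=ones * params["kappa_act"],
        h_act=ones * params["h_act"],
        kappa_inh=ones * params["kappa_inh"],
        h_inh=ones * params["h_inh"],
        delta=ones * params["delta"],
        depth=depth,
    )


def _propensities(model: ToggleSwitchModel, state: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Production and degradation rates for every trajectory and species."""
    g_s = state[:, model.partner]
    inh = model.kappa_inh**model.h_inh / (g_s**model.h_inh + model.kappa_inh**model.h_inh)
    has_up = model.upstream >= 0
    act = np.ones_like(state, dtype=float)
    if has_up.any():
        g_u = state[:, model.upstream[has_up]]
        with np.errstate(invalid="ignore"):
            a = g_u**model.h_act[has_up] / (
                g_u**model.h_act[has_up] + model.kappa_act[has_up]**model.h_act[has_up]
            )
        act[:, has_up] = np.where(g_u > 0, a, 0.0)
    prod = model.alpha * act * inh
    deg = model.delta * state
    return prod, deg


def tau_leap_simulate(
    model: ToggleSwitchModel,
    n_traj: int = 2000,
    t_end: float = 150.0,
    n_timepoints: int = 100,
    lambda_init: float = 100.0,
    dt: float = 0.1,
    seed: int = 0,
) -> SimulationRun:
    """Fixed-step tau-leaping from Poisson(lambda_init) initial counts.

    Each step draws Poisson event counts for every production and
    degradation channel at the current propensities; negative excursions
    are clamped to zero. States are recorded at ``n_timepoints`` uniform
    times from 0 to ``t_end``. A warning is raised if propensities change
    by more than 10% within a step (the leap condition), sampled on a
    subset of steps to stay cheap.
    """
    if t_end <= 0 or dt <= 0 or n_traj < 1:
        raise ValueError("t_end, dt and n_traj must be positive")
    rng = np.random.default_rng(seed)
    state = rng.poisson(lambda_init, size=(n_traj, model.n_species)).astype(float)
    time_grid = np.linspace(0.0, t_end, n_timepoints)
    out = np.empty((n_traj, n_timepoints, model.n_species), dtype=np.int64)
    out[:, 0] = state
    next_record = 1
    n_steps = int(np.ceil(t_end / dt))
    check_every = max(1, n_steps // 20)
    leap_warned = False
    t = 0.0
    for step in range(n_steps):
        prod, deg = _propensities(model, state)
        state = state + rng.poisson(prod * dt) - rng.poisson(deg * dt)
        np.maximum(state, 0.0, out=state)
        if not leap_warned and step % check_every == 0:
            prod2, deg2 = _propensities(model, state)
            denom = np.maximum(prod.mean() + deg.mean(), 1e-12)
            change = (np.abs(prod2 - prod).mean() + np.abs(deg2 - deg).mean()) / denom
            if change > 0.1:
                warnings.warn(
                    f"tau-leap accuracy: mean propensity changed by {change:.1%} in one "
                    "step; consider a smaller dt"
                )
                leap_warned = True
        t += dt
        while next_record < n_timepoints and time_grid[next_record] <= t + 1e-12:
            out[:, next_record] = state
            next_record += 1
    while next_record < n_timepoints:
        out[:, next_record] = state
        next_record += 1
    return SimulationRun(trajectories=out, time_grid=time_grid, seed=seed, model=model)


def _fate_labels(counts: np.ndarray, model: ToggleSwitchModel) -> list[str]:
    """Path-of-commitments label per cell: argmax protein of each switch along the path."""
    labels = []
    for row in counts:
        heap = 1  # virtual root; its children (heap 2, 3) form the root switch
        path = []
        for _ in range(model.depth):
            left, right = 2 * heap, 2 * heap + 1
            if left - 2 >= model.n_species:
                break
            choice = left if row[left - 2] >= row[right - 2] else right
            path.append("L" if choice == left else "R")
            heap = choice
        labels.append("/".join(path))
    return labels


def sample_cells_from_run(run: SimulationRun, n_cells: int, seed: int = 0) -> CellMatrix:
    """Snapshot matrix: uniform (trajectory, timepoint) pairs without replacement.

    The ground-truth fate label of each cell is the path of committed arms
    down the switch tree (the higher-count protein of each switch along the
    realised path) at the sampled time.
    """
    n_traj, n_tp, n_species = run.trajectories.shape
    total = n_traj * n_tp
    if n_cells > total:
        raise ValueError(f"cannot sample {n_cells} cells from {total} snapshots")
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n_cells, replace=False)
    traj_idx, tp_idx = np.divmod(flat, n_tp)
    counts = run.trajectories[traj_idx, tp_idx].astype(float)
    labels = _fate_labels(counts, run.model)
    return CellMatrix(
        values=counts,
        species_names=run.model.species_names(),
        cell_ids=[f"t{tr}_s{tp}" for tr, tp in zip(traj_idx, tp_idx)],
        labels=np.array(labels),
    )


def generate_geometry(
    kind: str,
    n_obs: int,
    d: int = 5,
    rho: float = 0.0,
    seed: int = 0,
    n_arms: int = 3,
    arm_lengths=None,
) -> CellMatrix:
    """Uniform samples on a named manifold embedded in d dimensions.

    Kinds: ``path`` (unit segment), ``star`` (``n_arms`` arms radiating
    from the origin in the first two coordinates, with ground-truth arm
    labels), ``circle`` (unit-radius circumference), ``blob`` (a point —
    i.e. pure Gaussian noise of SD ``rho``), ``triangle`` (filled 2-D
    triangle). Isotropic Gaussian noise of SD ``rho`` is added in all d
    dimensions.
    """
    if d < 2:
        raise ValueError("need d >= 2")
    rng = np.random.default_rng(seed)
    labels = None
    x = np.zeros((n_obs, d))
    if kind == "path":
        x[:, 0] = rng.random(n_obs)
    elif kind == "star":
        if arm_lengths is None:
            arm_lengths = np.ones(n_arms)
        arm_lengths = np.asarray(arm_lengths, dtype=float)
        if len(arm_lengths) != n_arms:
            raise ValueError("arm_lengths must have n_arms entries")
        arm = rng.integers(n_arms, size=n_obs)
        r = rng.random(n_obs) * arm_lengths[arm]
        theta = 2 * np.pi * arm / n_arms
        x[:, 0] = r * np.cos(theta)
        x[:, 1] = r * np.sin(theta)
        labels = arm.astype(str)
    elif kind == "circle":
        theta = 2 * np.pi * rng.random(n_obs)
        x[:, 0] = np.cos(theta)
        x[:, 1] = np.sin(theta)
    elif kind == "blob":
        pass  # a 0-D manifold: all structure comes from the noise term
    elif kind == "triangle":
        # k is irrelevant to data generation; any grid value works here
        return generate_triangle_dataset(ReferenceParams(n_obs=n_obs, d=d, k=50, rho=rho), seed=seed)
    else:
        raise ValueError(f"unknown geometry kind {kind!r}")
    if rho > 0:
        x += rng.normal(scale=rho, size=x.shape)
    return CellMatrix(
        values=x,
        species_names=[f"dim_{j}" for j in range(d)],
        labels=None if labels is None else np.asarray(labels),
    )
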