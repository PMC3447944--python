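"""Discrete one-dimensional random walk through the lymph node.

Lymphocytes enter at vertex 1 (the high endothelial venules), hop between
``n`` vertices with per-step probabilities of moving forward (``q_fwd``),
backward (``q_bwd``) or staying put (``q_stay``), and exit on reaching
vertex ``n`` (the efferent lymphatic). The transit-time law is the first
passage time from vertex 1 to vertex ``n``; each step lasts ``dt_min``
minutes. With the terminal vertex made absorbing, the entry ``[1, n]`` of
the k-th matrix power is the cumulative arrival probability by step k.

Boundary conventions: vertex 1 reflects (a backward move folds into
staying); vertex ``n`` absorbs for first-passage computation. For the
steady-state occupancy question the exit flux is instead reinjected at
vertex 1, balancing entry and exit as in an unchallenged node.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BIN_WIDTH_H, N_BINS, TransitDistribution
from .io import ConvolutionSystem

_MAX_KMAX = 10**6


@dataclass
class MCParams:
    """Random-walk parameters: step probabilities, vertex count, step length."""

    q_fwd: float
    q_bwd: float
    q_stay: float
    n_vertices: int = 10
    dt_min: float = 5.0

    def __post_init__(self) -> None:
        for name in ("q_fwd", "q_bwd", "q_stay"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if abs(self.q_fwd + self.q_bwd + self.q_stay - 1.0) > 1e-12:
            raise ValueError("step probabilities must sum to 1")
        if self.q_fwd <= 0:
            raise ValueError("q_fwd must be positive (otherwise no cell ever exits)")
        if self.n_vertices < 2:
            raise ValueError("need at least 2 vertices")
        if self.dt_min <= 0:
            raise ValueError("dt_min must be positive")

    @property
    def drift_ratio(self) -> float:
        """q_fwd / q_bwd; 1 means an undirected (zero-drift) walk."""
        return self.q_fwd / self.q_bwd if self.q_bwd > 0 else np.inf


@dataclass
class FirstPassageLaw:
    """First-passage probabilities ``f[k-1] = P(arrive exactly at step k)``."""

    f: np.ndarray
    dt_min: float
    tail_mass: float

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.size and self.f.min() < -1e-12:
            raise ValueError("negative first-passage probability")
        self.f = np.clip(self.f, 0.0, None)
        if abs(self.f.sum() + self.tail_mass - 1.0) > 1e-9:
            raise ValueError("first-passage law must conserve probability")

    @property
    def mean_h(self) -> float:
        """Mean first-passage time in hours over arrivals within the horizon."""
        k = np.arange(1, self.f.size + 1)
        return float(np.sum(k * self.f) * self.dt_min / 60.0)


def build_transition_matrix(params: MCParams) -> np.ndarray:
    """Transition matrix with reflecting entry and absorbing exit vertex."""
    n = params.n_vertices
    P = np.zeros((n, n))
    P[0, 0] = params.q_stay + params.q_bwd
    P[0, min(1, n - 1)] += params.q_fwd
    for i in range(1, n - 1):
        P[i, i - 1] += params.q_bwd
        P[i, i] += params.q_stay
        P[i, i + 1] += params.q_fwd
    P[n - 1, n - 1] = 1.0
    if np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-12):
        raise ValueError("rows of the transition matrix must sum to 1")
    return P


def first_passage_distribution(
    P: np.ndarray, k_max: int, dt_min: float = 1.0
) -> FirstPassageLaw:
    """First-passage law from vertex 1 to vertex n by iterated products.

    Uses repeated vector-matrix products (never dense matrix powers):
    the absorbing-state mass after k steps is the cumulative arrival
    probability, and its increments are the law.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > _MAX_KMAX:
        raise ValueError(f"k_max capped at {_MAX_KMAX}")
    n = P.shape[0]
    v = np.zeros(n)
    v[0] = 1.0
    f = np.empty(k_max)
    prev = 0.0
    for k in range(k_max):
        v = v @ P
        cum = v[n - 1]
        f[k] = cum - prev
        prev = cum
    return FirstPassageLaw(f=f, dt_min=dt_min, tail_mass=1.0 - prev)


def first_passage_law(params: MCParams, k_max: int | None = None) -> FirstPassageLaw:
    """Convenience wrapper: build the chain and cover the 100-hour horizon."""
    if k_max is None:
        k_max = int(np.ceil(N_BINS * BIN_WIDTH_H * 60.0 / params.dt_min))
    P = build_transition_matrix(params)
    return first_passage_distribution(P, k_max, dt_min=params.dt_min)


def bin_to_hours(law: FirstPassageLaw) -> TransitDistribution:
    """Aggregate step-indexed arrivals onto the 2-hour transit bins.

    Step k lands in bin ``(t-2, t]`` when ``k * dt_min`` lies in
    ``((t-2)*60, t*60]`` minutes. Mass arriving after 100 h joins the tail
    and is excluded from ``p`` without renormalisation.
    """
    k = np.arange(1, law.f.size + 1)
    t_minutes = k * law.dt_min
    bin_idx = np.ceil(t_minutes / (BIN_WIDTH_H * 60.0) - 1e-12).astype(int) - 1
    in_range = bin_idx < N_BINS
    p = np.bincount(bin_idx[in_range], weights=law.f[in_range], minlength=N_BINS)
    tail = law.tail_mass + float(law.f[~in_range].sum())
    return TransitDistribution(p, origin="mc", tail=tail)


def transit_distribution(params: MCParams, k_max: int | None = None) -> TransitDistribution:
    """First-passage law of ``params`` binned onto the 2-hour grid."""
    return bin_to_hours(first_passage_law(params, k_max))


DEFAULT_STAGE1_GRID = {
    "q_stay": tuple(np.round(np.arange(0.0, 1.0, 0.1), 1)),
    "ratio": (1 / 3, 0.5, 2 / 3, 0.8, 1.0, 1.25, 1.5, 2.0, 3.0),
    "n_vertices": tuple(range(5, 51, 5)),
    "dt_min": (1.0, 2.0, 5.0, 10.0),
}


def _params_from_ratio(q_stay: float, ratio: float, n: int, dt: float) -> MCParams:
    move = 1.0 - q_stay
    q_bwd = move / (1.0 + ratio)
    q_fwd = move - q_bwd
    return MCParams(q_fwd=q_fwd, q_bwd=q_bwd, q_stay=q_stay,
                    n_vertices=n, dt_min=dt)


def _train_sse(systems: list[ConvolutionSystem], dist: TransitDistribution) -> float:
    total = 0.0
    for s in systems:
        if s.c is None:
            raise ValueError("estimate c on every training system first")
        total += float(np.sum((s.c * s.B @ dist.p - s.L) ** 2))
    return total


def fit_mc(
    systems: list[ConvolutionSystem],
    grid_stage1: dict | None = None,
    k_max: int | None = None,
    refine: bool = True,
) -> tuple[MCParams, TransitDistribution, pd.DataFrame]:
    """Two-stage exhaustive fit of the random walk to efflux data.

    Stage 1 searches the coarse grid over ``q_stay``, the drift ratio
    ``q_fwd/q_bwd``, vertex count and step length, scoring each candidate by
    total efflux SSE over the training systems. Stage 2 fixes ``q_stay``,
    ``n_vertices`` and ``dt_min`` at their optima and refines ``(q_fwd,
    q_bwd)`` on a 0.01 grid. Returns the optimum, its binned transit
    distribution, and the SSE surface over the ``(q_stay, ratio)`` plane at
    the optimal ``(n_vertices, dt_min)`` for the drift heat map.
    """
    if not systems:
        raise ValueError("need at least one training system")
    grid = dict(DEFAULT_STAGE1_GRID)
    if grid_stage1:
        grid.update(grid_stage1)
    if any(len(grid[k]) == 0 for k in ("q_stay", "ratio", "n_vertices", "dt_min")):
        raise ValueError("empty parameter grid")

    records = []
    best = None  # (sse, params, dist)
    for q_stay, ratio, n, dt in itertools.product(
        grid["q_stay"], grid["ratio"], grid["n_vertices"], grid["dt_min"]
    ):
        params = _params_from_ratio(q_stay, ratio, n, dt)
        dist = transit_distribution(params, k_max)
        sse = _train_sse(systems, dist)
        records.append(
            {"q_stay": q_stay, "ratio": ratio, "n_vertices": n, "dt_min": dt,
             "sse": sse}
        )
        if best is None or sse < best[0]:
            best = (sse, params, dist)

    _, p1, d1 = best
    table = pd.DataFrame(records)
    surface = (
        table[(table.n_vertices == p1.n_vertices) & (table.dt_min == p1.dt_min)]
        [["q_stay", "ratio", "sse"]]
        .reset_index(drop=True)
    )

    if not refine:
        return p1, d1, surface

    # stage 2: fix q_stay, n, dt; (q_fwd, q_bwd) on a 0.01 grid
    move = 1.0 - p1.q_stay
    best2 = (best[0], p1, d1)
    for q_fwd in np.arange(0.01, move + 1e-9, 0.01):
        q_fwd = round(float(q_fwd), 2)
        q_bwd = round(move - q_fwd, 12)
        if q_bwd < 0:
            continue
        params = MCParams(q_fwd=q_fwd, q_bwd=q_bwd, q_stay=p1.q_stay,
                          n_vertices=p1.n_vertices, dt_min=p1.dt_min)
        dist = transit_distribution(params, k_max)
        sse = _train_sse(systems, dist)
        if sse < best2[0]:
            best2 = (sse, params, dist)
    return best2[1], best2[2], surface


def reinjection_matrix(params: MCParams) -> np.ndarray:
    """Closed-loop chain: exit flux from vertex n re-enters at vertex 1."""
    n = params.n_vertices
    P = np.zeros((n, n))
    P[0, 0] += params.q_stay + params.q_bwd
    P[0, min(1, n - 1)] += params.q_fwd
    for i in range(1, n - 1):
        P[i, i - 1] += params.q_bwd
        P[i, i] += params.q_stay
        P[i, i + 1] += params.q_fwd
    # terminal vertex behaves as interior, with its forward flux recycled
    P[n - 1, n - 2] += params.q_bwd
    P[n - 1, n - 1] += params.q_stay
    P[n - 1, 0] += params.q_fwd
    return P


def steady_state_occupancy(params: MCParams) -> np.ndarray:
    """Stationary occupancy across vertices under entry/exit balance.

    Solves ``pi P' = pi, sum(pi) = 1`` for the reinjection chain by a
    linear solve. Near zero drift the profile declines from the entry
    vertex toward the exit, i.e. cells accumulate near the HEVs.
    """
    if params.q_fwd <= 0:
        raise ValueError("chain is not irreducible without forward movement")
    P = reinjection_matrix(params)
    n = params.n_vertices
    M = P.T - np.eye(n)
    M[-1, :] = 1.0
    rhs = np.zeros(n)
    rhs[-1] = 1.0
    pi = np.linalg.solve(M, rhs)
    if pi.min() < -1e-10:
        raise ValueError("stationary solve produced negative occupancy")
    return np.clip(pi, 0.0, None)


def simulate_walkers(
    params: MCParams, n_walkers: int, k_max: int, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo first-passage step counts for ``n_walkers`` cells.

    Independent oracle for the matrix computation: each walker performs the
    chain until absorption or ``k_max`` steps; returns the arrival step per
    walker (0 marks non-arrival).
    """
    rng = np.random.default_rng(seed)
    n = params.n_vertices
    pos = np.zeros(n_walkers, dtype=np.int64)
    arrived = np.zeros(n_walkers, dtype=np.int64)
    active = np.arange(n_walkers)
    thresholds = np.array([params.q_bwd, params.q_bwd + params.q_stay])
    for k in range(1, k_max + 1):
        if active.size == 0:
            break
        u = rng.random(active.size)
        step = np.where(u < thresholds[0], -1, np.where(u < thresholds[1], 0, 1))
        pos_a = np.clip(pos[active] + step, 0, n - 1)
        pos[active] = pos_a
        done = pos_a == n - 1
        arrived[active[done]] = k
        active = active[~done]
    return arrived
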