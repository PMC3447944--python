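"""Synthetic cannulation experiments with known ground truth.

Two generators emulate the sheep experiment. The open-loop generator mirrors
the assumption the deconvolution itself makes: blood input decays
exponentially (labelled cells leave blood with mean lifetime ``tau``), and
efflux is a scaled lagged convolution of the gridded input with a known
transit distribution, sampled on a realistic schedule (dense early blood
sampling, then daily; lymph collected every few hours) with optional
measurement noise. The closed-loop generator is an agent simulation in
which a labelled cohort and an unlabelled background population actually
recirculate between blood and the node, so entry and exit balance at steady
state; it exists to quantify the bias the open-loop assumption introduces
and to check the occupancy and throughput identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .core import BIN_WIDTH_H, GRID_H, N_BINS, THETA_H, TransitDistribution
from .continuous import (
    GaussParams,
    IGParams,
    discretize_density,
    discretize_family,
    inverse_gaussian_cdf,
    inverse_gaussian_pdf,
)
from .io import (
    ConvolutionSystem,
    GriddedTimeCourse,
    TimeCourse,
    build_convolution_system,
)
from .randomwalk import MCParams, steady_state_occupancy, transit_distribution

TRANSIT_FAMILIES = ("inverse_gaussian", "mc", "mixture_of_two", "point_mass")
NOISE_MODELS = ("none", "gaussian_additive", "gaussian_multiplicative")
SCHEDULES = ("cannulation", "uniform_2h")

#: blood sampling times (hours): minutes-scale early draws, then hourly,
#: then daily - the typical cannulation protocol
CANNULATION_BLOOD_TIMES_H = np.array(
    [2 / 60, 5 / 60, 10 / 60, 20 / 60, 0.5, 1, 2, 3, 4, 6, 12, 24, 48, 72, 96, 120.0]
)
#: lymph collection times (hours): every 4 h to 48 h, then every 8 h
CANNULATION_LYMPH_TIMES_H = np.concatenate(
    [np.arange(4.0, 49.0, 4.0), np.arange(56.0, 97.0, 8.0), [100.0]]
)


@dataclass
class TruthSpec:
    """Ground truth and observation model for one synthetic experiment."""

    transit_family: str = "inverse_gaussian"
    family_params: dict[str, Any] = field(default_factory=lambda: {"mu": 30.0, "lam": 60.0})
    blood_tau: float = 7.3
    blood_b0: float = 2.0
    c_true: float = 1.0
    noise_model: str = "none"
    noise_param: float = 0.05
    schedule: str = "cannulation"
    seed: int = 0
    # closed-loop only
    n_cells: int = 20_000
    labelled_frac: float = 0.1
    sim_hours: float = 160.0

    def __post_init__(self) -> None:
        if self.transit_family not in TRANSIT_FAMILIES:
            raise ValueError(
                f"unknown transit family {self.transit_family!r}; "
                f"choose one of {TRANSIT_FAMILIES}"
            )
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.schedule not in SCHEDULES:
            raise ValueError(f"unknown schedule {self.schedule!r}")
        if self.blood_tau <= 0 or self.blood_b0 <= 0 or self.c_true < 0:
            raise ValueError("blood_tau, blood_b0 must be positive; c_true nonnegative")


@dataclass
class SimResult:
    """A synthetic experiment: observations plus the truth that made them."""

    timecourse: TimeCourse
    truth: TransitDistribution
    c_true: float
    diagnostics: dict[str, Any] = field(default_factory=dict)


def make_truth(spec: TruthSpec) -> TransitDistribution:
    """The binned true transit distribution for a spec.

    Mixtures of two inverse Gaussians produce the bimodal truths that probe
    whether secondary peaks survive the inference.
    """
    fam, fp = spec.transit_family, spec.family_params
    if fam == "point_mass":
        t = float(fp["t_h"])
        if not 0 < t <= N_BINS * BIN_WIDTH_H:
            raise ValueError("point mass must lie in (0, 100] h")
        p = np.zeros(N_BINS)
        p[int(np.ceil(t / BIN_WIDTH_H - 1e-12)) - 1] = 1.0
        return TransitDistribution(p, origin="truth")
    if fam == "inverse_gaussian":
        d = discretize_family("inverse_gaussian", IGParams(**fp))
        return TransitDistribution(d.p, origin="truth", tail=d.tail)
    if fam == "mixture_of_two":
        w = float(fp["weight"])
        if not 0 <= w <= 1:
            raise ValueError("mixture weight must lie in [0, 1]")
        c1, c2 = IGParams(fp["mu1"], fp["lam1"]), IGParams(fp["mu2"], fp["lam2"])
        pdf = lambda t, _: (w * inverse_gaussian_pdf(t, c1)
                            + (1 - w) * inverse_gaussian_pdf(t, c2))
        cdf = lambda t, _: (w * inverse_gaussian_cdf(t, c1)
                            + (1 - w) * inverse_gaussian_cdf(t, c2))
        d = discretize_density(pdf, None, cdf=cdf)
        return TransitDistribution(d.p, origin="truth", tail=d.tail)
    # fam == "mc"
    d = transit_distribution(MCParams(**fp))
    return TransitDistribution(d.p, origin="truth", tail=d.tail)


def _blood(spec: TruthSpec, t_h: np.ndarray) -> np.ndarray:
    return spec.blood_b0 * np.exp(-np.asarray(t_h, float) / spec.blood_tau)


def _apply_noise(values: np.ndarray, spec: TruthSpec, rng) -> np.ndarray:
    if spec.noise_model == "none":
        return values
    if spec.noise_model == "gaussian_additive":
        noisy = values + rng.normal(0.0, spec.noise_param, size=values.shape)
    else:  # multiplicative, coefficient of variation
        noisy = values * (1.0 + spec.noise_param * rng.normal(size=values.shape))
    return np.clip(noisy, 0.0, None)


def true_system(spec: TruthSpec) -> tuple[ConvolutionSystem, TransitDistribution]:
    """The noise-free gridded system a spec implies (c already set)."""
    truth = make_truth(spec)
    g = GriddedTimeCourse(
        animal_id=f"synthetic-{spec.seed}",
        blood=_blood(spec, GRID_H),
        lymph=np.zeros(N_BINS),
        method="linear",
    )
    sys = build_convolution_system(g)
    sys.L = spec.c_true * sys.B @ truth.p
    sys.c = spec.c_true
    return sys, truth


def simulate_open_loop(spec: TruthSpec) -> SimResult:
    """Generate one synthetic cannulation experiment.

    Blood follows the exponential decay exactly; gridded lymph is
    ``c_true * B @ p_true`` by construction, sampled at the schedule and
    perturbed by the noise model. Labelled cells returning to blood after
    transit are deliberately ignored here (the measured blood curve, not a
    model of it, drives the deconvolution); the closed-loop simulator
    quantifies that bias.
    """
    rng = np.random.default_rng(spec.seed)
    sys, truth = true_system(spec)
    L_grid = sys.L

    if spec.schedule == "uniform_2h":
        t_blood = np.concatenate([[0.0], GRID_H])
        t_lymph = GRID_H.copy()
    else:
        t_blood = CANNULATION_BLOOD_TIMES_H.copy()
        t_lymph = CANNULATION_LYMPH_TIMES_H.copy()

    blood_obs = _apply_noise(_blood(spec, t_blood), spec, rng)
    # lymph times sit on the 2-h grid by construction
    idx = np.round(t_lymph / BIN_WIDTH_H).astype(int) - 1
    lymph_obs = _apply_noise(L_grid[idx], spec, rng)

    times = np.unique(np.concatenate([t_blood, t_lymph]))
    pb = np.full(times.size, np.nan)
    pl = np.full(times.size, np.nan)
    pb[np.searchsorted(times, t_blood)] = blood_obs
    pl[np.searchsorted(times, t_lymph)] = lymph_obs
    tc = TimeCourse(
        animal_id=f"synthetic-{spec.seed}", time_h=times, pct_blood=pb, pct_lymph=pl
    )
    diag = {"truth_tail_mass": truth.tail, "schedule": spec.schedule}
    return SimResult(timecourse=tc, truth=truth, c_true=spec.c_true, diagnostics=diag)


def simulate_cohort(
    spec: TruthSpec, n_systems: int, base_seed: int | None = None
) -> list[SimResult]:
    """Independent replicate experiments sharing one truth (seeds offset)."""
    base = spec.seed if base_seed is None else base_seed
    out = []
    for i in range(n_systems):
        s = TruthSpec(**{**spec.__dict__, "seed": base + i})
        out.append(simulate_open_loop(s))
    return out


def brownian_first_passage_sample(
    d: float,
    v: float,
    n_samples: int,
    dt: float = 1e-3,
    seed: int = 0,
    t_max: float | None = None,
    barrier_correction: bool = True,
) -> np.ndarray:
    """Euler-Maruyama first-passage times of Brownian motion with drift.

    Simulates ``X_{k+1} = X_k + v dt + sqrt(dt) Z`` (unit variance) from 0
    and records the first time each path reaches the barrier ``d``; the
    exact law is IG(mu = d/v, lam = d**2). Discrete monitoring misses
    excursions between steps, inflating passage times by O(sqrt(dt)); the
    standard continuity correction lowers the barrier by
    ``0.5826 * sqrt(dt)`` to cancel that bias. Non-arrivals by ``t_max``
    come back as NaN.
    """
    if d <= 0 or v <= 0:
        raise ValueError("d and v must be positive")
    rng = np.random.default_rng(seed)
    if t_max is None:
        t_max = 30.0 * d / v
    barrier = d - 0.5826 * np.sqrt(dt) if barrier_correction else d
    n_steps = int(np.ceil(t_max / dt))
    x = np.zeros(n_samples)
    t_hit = np.full(n_samples, np.nan)
    active = np.arange(n_samples)
    sqdt = np.sqrt(dt)
    for k in range(1, n_steps + 1):
        x[active] += v * dt + sqdt * rng.standard_normal(active.size)
        hit = x[active] >= barrier
        t_hit[active[hit]] = k * dt
        active = active[~hit]
        if active.size == 0:
            break
    return t_hit


def simulate_closed_loop(spec: TruthSpec) -> SimResult:
    """Agent-based recirculation: blood -> node random walk -> blood.

    Every cell is tracked individually. Blood residence is exponential with
    mean ``blood_tau``; inside the node cells perform the discrete walk,
    exiting back to blood from the last vertex on a forward move (the
    reinjection chain). After a burn-in that lets the unlabelled background
    reach steady state, a cohort is labelled in blood and followed to
    washout. Diagnostics report the throughput identity
    mean transit time = (cells in node) / (cells entering per hour)
    and the time-averaged occupancy profile.
    """
    if spec.transit_family != "mc":
        raise ValueError("closed-loop simulation requires an mc transit family")
    params = MCParams(**spec.family_params)
    if spec.n_cells < 1000:
        raise ValueError("cohort below 1000 cells is too noisy to be useful")
    n_lab = int(round(spec.n_cells * spec.labelled_frac))

    rng = np.random.default_rng(spec.seed)
    n = params.n_vertices
    dt_h = params.dt_min / 60.0
    p_enter = 1.0 - np.exp(-dt_h / spec.blood_tau)
    thr_bwd = params.q_bwd
    thr_stay = params.q_bwd + params.q_stay

    n_cells = spec.n_cells
    # state: -1 blood, 0..n-1 node vertex
    state = np.full(n_cells, -1, dtype=np.int64)
    entry_step = np.zeros(n_cells, dtype=np.int64)
    labelled = np.zeros(n_cells, dtype=bool)

    # burn-in long enough for several blood+node cycles of the background
    burn_steps = int(np.ceil(200.0 / dt_h))
    sim_steps = int(np.ceil(spec.sim_hours / dt_h))
    sample_every = max(1, int(round(2.0 / dt_h)))  # 2-hour observation cadence

    occupancy = np.zeros(n)
    entries = 0
    exits = 0
    transit_steps_sum = 0.0
    transit_batches: list[float] = []
    nf_batches: list[float] = []
    batch = max(1, sim_steps // 10)
    b_entries = b_occ = b_exits = b_tsum = 0.0

    times, blood_pct, lymph_pct = [], [], []

    def step(k: int, measure: bool):
        nonlocal entries, exits, transit_steps_sum, occupancy
        nonlocal b_entries, b_occ, b_exits, b_tsum
        u = rng.random(n_cells)
        in_blood = state == -1
        entering = in_blood & (u < p_enter)
        in_node = ~in_blood
        move = np.zeros(n_cells, dtype=np.int64)
        move[in_node & (u < thr_bwd)] = -1
        move[in_node & (u >= thr_stay)] = 1
        new_state = state.copy()
        pos = np.clip(state[in_node] + move[in_node], 0, n)  # n marks exit
        exiting_mask = pos == n
        node_idx = np.flatnonzero(in_node)
        new_state[node_idx] = pos
        new_state[node_idx[exiting_mask]] = -1
        new_state[entering] = 0
        if measure:
            counts = np.bincount(state[in_node], minlength=n)
            occupancy += counts
            n_ent = int(entering.sum())
            n_ex = int(exiting_mask.sum())
            entries += n_ent
            exits += n_ex
            tsum = float((k - entry_step[node_idx[exiting_mask]]).sum())
            transit_steps_sum += tsum
            b_entries += n_ent
            b_occ += counts.sum()
            b_exits += n_ex
            b_tsum += tsum
        entry_step[entering] = k
        state[:] = new_state
        return node_idx[exiting_mask]

    # burn-in: unlabelled background reaches steady state
    for k in range(-burn_steps, 0):
        step(k, measure=False)

    # label a cohort currently in blood (the infusion)
    if n_lab > 0:
        blood_idx = np.flatnonzero(state == -1)
        if blood_idx.size < n_lab:
            raise ValueError("not enough cells in blood to label the cohort")
        labelled[rng.choice(blood_idx, size=n_lab, replace=False)] = True
    conservation_ok = True

    window_exits_lab = 0
    window_exits_tot = 0
    for k in range(sim_steps):
        exited = step(k, measure=True)
        window_exits_lab += int(labelled[exited].sum())
        window_exits_tot += int(exited.size)
        if (k + 1) % batch == 0 and b_exits > 0 and b_entries > 0:
            transit_batches.append(b_tsum / b_exits * dt_h)
            nf_batches.append((b_occ / batch) / (b_entries / (batch * dt_h)))
            b_entries = b_occ = b_exits = b_tsum = 0.0
        if (k + 1) % sample_every == 0:
            t_h = (k + 1) * dt_h
            in_blood = state == -1
            nb = int(in_blood.sum())
            times.append(t_h)
            blood_pct.append(100.0 * labelled[in_blood].sum() / nb if nb else np.nan)
            lymph_pct.append(
                100.0 * window_exits_lab / window_exits_tot
                if window_exits_tot else np.nan
            )
            window_exits_lab = window_exits_tot = 0
        if labelled.sum() != n_lab:
            conservation_ok = False

    mean_transit_h = transit_steps_sum / exits * dt_h if exits else np.nan
    mean_node = occupancy.sum() / sim_steps
    entries_per_h = entries / (sim_steps * dt_h)
    n_over_f = mean_node / entries_per_h if entries_per_h else np.nan
    tb, nb_ = np.array(transit_batches), np.array(nf_batches)
    se = float(np.sqrt(tb.var(ddof=1) / tb.size + nb_.var(ddof=1) / nb_.size)) \
        if tb.size > 1 else np.nan

    occ_profile = occupancy / occupancy.sum() if occupancy.sum() else occupancy
    truth = transit_distribution(params)
    tc = TimeCourse(
        animal_id=f"closedloop-{spec.seed}",
        time_h=np.array(times),
        pct_blood=np.array(blood_pct),
        pct_lymph=np.array(lymph_pct),
    )
    diag = {
        "mean_transit_h": float(mean_transit_h),
        "n_over_f_h": float(n_over_f),
        "littles_law_se_h": se,
        "occupancy": occ_profile,
        "occupancy_expected": steady_state_occupancy(params),
        "entries_per_h": float(entries_per_h),
        "mean_node_count": float(mean_node),
        "label_conserved": conservation_ok,
        "n_labelled": int(n_lab),
    }
    return SimResult(timecourse=tc, truth=truth, c_true=spec.c_true, diagnostics=diag)
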