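"""Goodness-of-fit and the side-by-side model comparison.

All models are scored the same way: their transit distribution predicts
efflux through each held-out animal's own convolution system (with that
animal's ``c``), and the sum of squared errors against observed efflux on
the 50-point grid is reported per animal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FitResult, TransitDistribution
from .deconv import SLassoConfig, concat_and_tune, estimate_c
from .io import ConvolutionSystem

MODELS = ("lasso", "slasso", "mc", "inverse_gaussian", "gaussian")


def sse(pred: np.ndarray, obs: np.ndarray) -> float:
    """Sum of squared errors on the percent scale."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    return float(np.sum((pred - obs) ** 2))


def _per_system_sse(systems: list[ConvolutionSystem], p: np.ndarray) -> dict[str, float]:
    out = {}
    for s in systems:
        c = s.c if s.c is not None else estimate_c(s)
        out[s.animal_id] = sse(c * s.B @ p, s.L)
    return out


def compare_models(
    systems: list[ConvolutionSystem],
    split: tuple[list[int], list[int]],
    seed: int = 0,
    models: tuple[str, ...] = MODELS,
    slasso_cfg: SLassoConfig | None = None,
    mc_grid: dict | None = None,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit every requested model on the training split, score on the test split.

    Returns the per-test-animal SSE table (one column per model, ``NaN``
    where a model failed) and the fitted results. The same training systems
    are used for every model; failures are recorded, never fatal.
    """
    train_ids, test_ids = split
    if set(train_ids) & set(test_ids):
        raise ValueError("train and test splits must be disjoint")
    train = [systems[i] for i in train_ids]
    test = [systems[i] for i in test_ids]
    for s in systems:
        if s.c is None:
            estimate_c(s)

    fits: dict[str, FitResult] = {}
    for model in models:
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}")
        try:
            fits[model] = _fit_one(model, train, test, seed, slasso_cfg, mc_grid)
        except Exception:  # recorded as missing in the table
            fits[model] = None

    rows = []
    for s in test:
        row = {"system_id": s.animal_id}
        for model in models:
            fr = fits.get(model)
            row[f"sse_{model}"] = fr.test_sse.get(s.animal_id, np.nan) if fr else np.nan
        rows.append(row)
    return pd.DataFrame(rows), fits


def _fit_one(model, train, test, seed, slasso_cfg, mc_grid) -> FitResult:
    # imported lazily to keep module import acyclic
    from .continuous import fit_continuous
    from .deconv import solve_lasso
    from .randomwalk import fit_mc

    if model in ("inverse_gaussian", "gaussian"):
        return fit_continuous(train, model, test_systems=test)
    if model == "mc":
        params, dist, _ = fit_mc(train, grid_stage1=mc_grid)
        train_sse = sum(_per_system_sse(train, dist.p).values())
        return FitResult(
            model="mc",
            params={"q_fwd": params.q_fwd, "q_bwd": params.q_bwd,
                    "q_stay": params.q_stay, "n_vertices": params.n_vertices,
                    "dt_min": params.dt_min},
            distribution=dist, train_sse=train_sse,
            test_sse=_per_system_sse(test, dist.p),
        )
    if model == "slasso":
        cfg = slasso_cfg or SLassoConfig(seed=seed, n_train=min(3, len(train)))
        lam, dist, _ = concat_and_tune(train, cfg)
        train_sse = sum(_per_system_sse(train, dist.p).values())
        return FitResult(model="slasso", params={"lambda": lam}, distribution=dist,
                         train_sse=train_sse, test_sse=_per_system_sse(test, dist.p))
    # plain LASSO: one concatenated training regression, no smoothing
    from .deconv import _solve_simplex_ls, _stack_training

    A, b = _stack_training(train, range(len(train)))
    p = _solve_simplex_ls(A, b)
    dist = TransitDistribution(p, origin="lasso")
    train_sse = sum(_per_system_sse(train, dist.p).values())
    return FitResult(model="lasso", params={}, distribution=dist,
                     train_sse=train_sse, test_sse=_per_system_sse(test, dist.p))
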