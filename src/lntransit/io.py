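"""Reading cannulation time courses and assembling the convolution system.

A cannulation experiment yields two irregularly sampled channels: the
percentage of CFSE-labelled cells in blood (the input to the node) and in
efferent lymph (the output). Irregular samples are interpolated onto the
common 2-hour grid, from which the lower-triangular lagged-input matrix ``B``
of the efflux model ``L = c * B @ p`` is built.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .core import BIN_WIDTH_H, GRID_H, N_BINS

INTERP_METHODS = ("linear", "cubic_spline")


@dataclass
class TimeCourse:
    """One animal's irregular (time, %blood, %lymph) samples.

    Times are strictly increasing; missing values are NaN per channel.
    Each channel needs at least two finite observations within [0, 100] h.
    """

    animal_id: str
    time_h: np.ndarray
    pct_blood: np.ndarray
    pct_lymph: np.ndarray

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.pct_blood = np.asarray(self.pct_blood, dtype=float)
        self.pct_lymph = np.asarray(self.pct_lymph, dtype=float)
        n = self.time_h.size
        if self.pct_blood.size != n or self.pct_lymph.size != n:
            raise ValueError("channel lengths differ from time vector")
        if n and self.time_h.min() < 0:
            raise ValueError("negative time")
        if np.any(np.diff(self.time_h) == 0):
            raise ValueError(f"duplicate time in {self.animal_id}")
        if np.any(np.diff(self.time_h) < 0):
            raise ValueError("times must be strictly increasing (sort first)")
        for name, ch in (("pct_blood", self.pct_blood), ("pct_lymph", self.pct_lymph)):
            finite = np.isfinite(ch)
            if np.any(ch[finite] < 0):
                raise ValueError(f"negative percent in {name}")
            usable = finite & (self.time_h >= 0) & (self.time_h <= 100)
            if usable.sum() < 2:
                raise ValueError(
                    f"{name} needs >=2 finite observations in [0, 100] h, "
                    f"got {int(usable.sum())}"
                )


@dataclass
class GriddedTimeCourse:
    """Blood and lymph percentages interpolated onto t = 2, 4, ..., 100 h."""

    animal_id: str
    blood: np.ndarray
    lymph: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.blood = np.asarray(self.blood, dtype=float)
        self.lymph = np.asarray(self.lymph, dtype=float)
        for name, ch in (("blood", self.blood), ("lymph", self.lymph)):
            if ch.shape != (N_BINS,):
                raise ValueError(f"{name} must have {N_BINS} grid values")
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"{name} contains non-finite values")
            if ch.min() < 0:
                raise ValueError(f"{name} contains negative values")

    @property
    def grid(self) -> np.ndarray:
        return GRID_H.copy()


@dataclass
class ConvolutionSystem:
    """The gridded regression system ``L ~= c * B @ p``.

    ``B[i, j]`` holds the blood percentage a lag ``theta_j = 2j`` hours
    before observation time ``t_i = 2(i+1)``; it is lower triangular because
    efflux cannot depend on future input. ``c`` is the proportionality
    constant between blood and lymph percentages, unset until estimated.
    """

    animal_id: str
    B: np.ndarray
    L: np.ndarray
    c: float | None = None

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if self.B.shape != (N_BINS, N_BINS):
            raise ValueError(f"B must be {N_BINS}x{N_BINS}")
        if self.L.shape != (N_BINS,):
            raise ValueError(f"L must have {N_BINS} entries")
        if np.any(np.triu(self.B, k=1) != 0):
            raise ValueError("B must be lower triangular (causality)")
        if self.B.min() < 0 or self.L.min() < 0:
            raise ValueError("B and L must be nonnegative")


def read_timecourse(path: str | Path, animal_id: str | None = None) -> TimeCourse:
    """Read one animal's CSV with columns ``time_h,pct_blood,pct_lymph``.

    Rows are sorted by time; duplicate times, negative percentages, or fewer
    than two usable rows per channel raise ``ValueError``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"time_h", "pct_blood", "pct_lymph"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    df = df.sort_values("time_h", kind="stable")
    return TimeCourse(
        animal_id=animal_id or path.stem,
        time_h=df["time_h"].to_numpy(float),
        pct_blood=df["pct_blood"].to_numpy(float),
        pct_lymph=df["pct_lymph"].to_numpy(float),
    )


def read_manifest(path: str | Path) -> list[TimeCourse]:
    """Read a manifest CSV (columns ``animal_id,file``) of per-animal tables.

    Relative file paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if not {"animal_id", "file"} <= set(df.columns):
        raise ValueError("manifest needs columns animal_id,file")
    out = []
    for row in df.itertuples(index=False):
        f = Path(row.file)
        if not f.is_absolute():
            f = path.parent / f
        out.append(read_timecourse(f, animal_id=str(row.animal_id)))
    return out


def _interp_channel(t_obs: np.ndarray, y_obs: np.ndarray, method: str) -> np.ndarray:
    keep = np.isfinite(y_obs)
    t, y = t_obs[keep], y_obs[keep]
    if method == "linear":
        # np.interp holds the boundary values flat outside [t[0], t[-1]]
        vals = np.interp(GRID_H, t, y)
    elif method == "cubic_spline":
        spline = CubicSpline(t, y)
        vals = spline(np.clip(GRID_H, t[0], t[-1]))
    else:
        raise ValueError(f"unknown interpolation method {method!r}; "
                         f"choose one of {INTERP_METHODS}")
    return np.clip(vals, 0.0, None)


def interpolate_to_grid(tc: TimeCourse, method: str = "linear") -> GriddedTimeCourse:
    """Interpolate both channels onto the 2-hour grid.

    Interpolation, not smoothing: values at observed times equal the
    observations. Outside the observed span values are held flat at the
    nearest observation, and negative spline excursions are clipped to zero
    (percentages cannot be negative).
    """
    return GriddedTimeCourse(
        animal_id=tc.animal_id,
        blood=_interp_channel(tc.time_h, tc.pct_blood, method),
        lymph=_interp_channel(tc.time_h, tc.pct_lymph, method),
        method=method,
    )


def build_convolution_system(g: GriddedTimeCourse) -> ConvolutionSystem:
    """Assemble the lagged-input matrix ``B`` and efflux vector ``L``.

    ``B[i, j] = blood(t_i - theta_j)`` for ``theta_j <= t_i`` and zero
    otherwise. The lag exactly equal to the observation time refers to blood
    at t = 0, which is not on the grid; the gridded value at the smallest
    grid time (2 h) is used in its place.
    """
    B = np.zeros((N_BINS, N_BINS))
    for i in range(N_BINS):
        for j in range(i + 1):
            # t_i - theta_j = 2(i - j); grid index i-j-1, with 2(i-j)=0
            # falling back to the first grid value
            B[i, j] = g.blood[max(i - j - 1, 0)]
    return ConvolutionSystem(animal_id=g.animal_id, B=B, L=g.lymph.copy())


def write_gridded(g: GriddedTimeCourse, path: str | Path) -> None:
    """Write a gridded time course as CSV (t_h, blood_pct, lymph_pct, method)."""
    pd.DataFrame(
        {"t_h": GRID_H, "blood_pct": g.blood, "lymph_pct": g.lymph,
         "method": g.method}
    ).to_csv(path, index=False)


def write_timecourse(tc: TimeCourse, path: str | Path) -> None:
    """Write a time course back to the delimited-text exchange format."""
    pd.DataFrame(
        {"time_h": tc.time_h, "pct_blood": tc.pct_blood, "pct_lymph": tc.pct_lymph}
    ).to_csv(path, index=False)
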