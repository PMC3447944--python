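"""Shared containers and the common 2-hour analysis grid.

Everything downstream works on a fixed discretisation of the first 100 hours
of a cannulation experiment: 50 two-hour bins. Observation times and transit
bin right edges coincide at t = 2, 4, ..., 100 h. Transit bin j covers the
half-open interval (2(j-1), 2j] hours, so there is no zero-lag bin: a cell
needs a nonzero time to cross from the high endothelial venules to the
efferent lymphatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: number of transit bins / gridded observation times
N_BINS = 50
#: bin width in hours
BIN_WIDTH_H = 2.0
#: gridded observation times t = 2, 4, ..., 100 h
GRID_H = np.arange(1, N_BINS + 1) * BIN_WIDTH_H
#: transit bin right edges theta_j = 2j h (identical to GRID_H by construction)
THETA_H = GRID_H

_SUM_TOL = 1e-6
_NEG_TOL = 1e-9


@dataclass
class TransitDistribution:
    """A probability distribution of lymph-node transit times on the 2-h grid.

    Parameters
    ----------
    p
        Probability of a transit time in bin ``(2(j-1), 2j]`` hours,
        ``j = 1..50``.
    origin
        Which procedure produced the distribution: ``lasso``, ``slasso``,
        ``mc``, ``inverse_gaussian``, ``gaussian`` or ``truth``.
    tail
        Probability mass beyond 100 h (or, for a Gaussian comparator, at
        negative times). Regression solutions are constrained to the simplex
        and have ``tail == 0``; mechanistic models may truncate.

    The invariant ``sum(p) + tail == 1`` (to 1e-6) is enforced on
    construction; entries in ``(-1e-9, 0)`` are clipped to zero.
    """

    p: np.ndarray
    origin: str = "truth"
    tail: float = 0.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (N_BINS,):
            raise ValueError(f"p must have shape ({N_BINS},), got {self.p.shape}")
        if not np.all(np.isfinite(self.p)):
            raise ValueError("p contains non-finite entries")
        if self.p.min() < -_NEG_TOL:
            raise ValueError(f"negative probability {self.p.min():g} below tolerance")
        self.p = np.clip(self.p, 0.0, None)
        total = self.p.sum() + self.tail
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"sum(p) + tail = {total:g}, expected 1")

    def normalized(self) -> "TransitDistribution":
        """Return the distribution renormalised onto the 100-h support."""
        s = self.p.sum()
        if s <= 0:
            raise ValueError("cannot normalise a zero distribution")
        return TransitDistribution(self.p / s, origin=self.origin, tail=0.0)


@dataclass
class FitResult:
    """Outcome of fitting one transit-time model family to efflux data.

    ``test_sse`` maps held-out system identifiers to the sum of squared
    errors between predicted and observed efflux on the 50-point grid
    (percent scale), matching how goodness-of-fit is reported per animal.
    """

    model: str
    params: dict[str, Any]
    distribution: TransitDistribution
    train_sse: float
    test_sse: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.train_sse < 0:
            raise ValueError("SSE must be nonnegative")

    @property
    def mean_test_sse(self) -> float:
        vals = [v for v in self.test_sse.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")
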