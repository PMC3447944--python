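"""Reported per-animal summaries from the sheep cannulation experiments.

Seventeen long-term single lymph-node cannulations (prescapular or popliteal,
merino ewes) underlie this analysis; the raw time courses were never
deposited, but the per-animal summary statistics were reported and serve as
inputs for cross-animal summaries: the mean lifetime of labelled cells in
blood before trans-endothelial migration, and the median/mean lymph-node
migration times from the per-animal deconvolved distributions.
"""

from __future__ import annotations

#: mean lifetime of labelled T cells in blood, hours, per animal
BLOOD_LIFETIMES_H: dict[str, float] = {
    "B445a": 6.4,
    "B445b": 5.3,
    "B481": 9.7,
    "B687": 7.5,
    "B857a": 20.6,
    "B857b": 10.5,
    "R153a": 7.1,
    "R153b": 10.3,
    "R401": 6.4,
    "R632": 7.2,
    "R634": 10.3,
    "R705": 6.4,
    "R797": 7.2,
    "R798": 10.3,
    "R890": 7.3,
    "Y044a": 8.0,
    "Y044b": 6.3,
}

#: per-animal (median_h, mean_h) lymph-node migration times from the
#: deconvolved transit-time distributions
TRANSIT_TIMES_H: dict[str, tuple[float, float]] = {
    "B445a": (34.0, 40.1),
    "B445b": (36.0, 44.8),
    "B481": (36.0, 41.9),
    "B687": (22.0, 34.2),
    "B857a": (24.0, 30.2),
    "B857b": (26.0, 29.3),
    "R153a": (26.0, 31.4),
    "R153b": (26.0, 26.0),
    "R401": (18.0, 29.8),
    "R632": (26.0, 34.4),
    "R634": (14.0, 17.6),
    "R705": (22.0, 24.3),
    "R797": (22.0, 29.9),
    "R798": (22.0, 26.1),
    "R890": (22.0, 24.6),
    "Y044a": (26.0, 34.3),
    "Y044b": (30.0, 34.0),
}
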