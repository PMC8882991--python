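"""Occupancy-frequency curves and core-satellite classification.

For one niche, the occupancy of an ASV is the number of samples in which
it is present; the curve tallies how many ASVs sit at each occupancy
level. A bimodal curve — many ASVs seen in a single sample (satellites)
plus a secondary mode of ASVs present in nearly all samples (the core) —
is the classic core-satellite pattern. The classification rule here is an
operational heuristic (endpoint modes versus the interior minimum), fully
configurable; the pattern itself has no universally agreed test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .table import AsvTable


@dataclass
class OccupancyCurve:
    niche: str
    n_samples: int
    frequency: dict[int, int]  # occupancy count k (1..n) -> number of ASVs

    def total_asvs(self) -> int:
        return sum(self.frequency.values())

    def to_frame(self) -> pd.DataFrame:
        ks = sorted(self.frequency)
        return pd.DataFrame(
            {
                "occupancy_count": ks,
                "occupancy_fraction": [k / self.n_samples for k in ks],
                "frequency": [self.frequency[k] for k in ks],
            }
        )


def occupancy_frequency(niche_table: AsvTable, niche: str = "") -> OccupancyCurve:
    """Tally ASVs by the number of samples they occupy in one niche.

    ASVs absent from every sample are excluded from the curve.
    """
    counts = niche_table.counts
    n = counts.shape[0]
    if n < 1:
        raise ValueError("occupancy_frequency requires >= 1 sample")
    occ = (counts > 0).sum(axis=0)
    occ = occ[occ > 0]
    freq = occ.value_counts().sort_index()
    return OccupancyCurve(niche, n, {int(k): int(v) for k, v in freq.items()})


def classify_core_satellite(
    curve: OccupancyCurve,
    core_quantile: float = 0.9,
    core_factor: float = 2.0,
) -> tuple[str, dict]:
    """Classify a curve as core_satellite / satellite_only / uniform / indeterminate.

    Rule: the curve must peak at occupancy 1 (satellite mode); it is
    ``core_satellite`` when, in addition, the maximum frequency over the
    core bins (k >= core_quantile * n) exceeds ``core_factor`` times the
    interior minimum (with a floor of 1 so an empty interior bin cannot
    make any nonzero core a mode). A satellite peak with no such core mode
    is ``satellite_only``; an everywhere-equal curve is ``uniform``; all
    other shapes are ``indeterminate``. The decision trace is returned.
    """
    n = curve.n_samples
    if n < 3:
        raise ValueError("classification requires n_samples >= 3")
    freq = {k: curve.frequency.get(k, 0) for k in range(1, n + 1)}
    values = list(freq.values())
    core_start = max(2, math.ceil(core_quantile * n))
    core_bins = {k: freq[k] for k in range(core_start, n + 1)}
    interior_bins = {k: freq[k] for k in range(2, core_start)}
    trace: dict = {
        "n_samples": n,
        "core_start": core_start,
        "satellite_freq": freq[1],
        "max_freq": max(values),
        "core_max": max(core_bins.values()) if core_bins else 0,
        "interior_min": min(interior_bins.values()) if interior_bins else None,
        "core_factor": core_factor,
    }
    if len(set(values)) == 1:
        trace["rule"] = "all bins equal"
        return "uniform", trace
    satellite_mode = freq[1] == trace["max_freq"] and freq[1] > 0
    trace["satellite_mode"] = satellite_mode
    if not satellite_mode:
        trace["rule"] = "no satellite peak at k=1"
        return "indeterminate", trace
    if not interior_bins:
        trace["rule"] = "no interior bins"
        return "indeterminate", trace
    threshold = core_factor * max(trace["interior_min"], 1)
    trace["core_threshold"] = threshold
    if trace["core_max"] >= threshold:
        trace["rule"] = "satellite peak + core mode above interior minimum"
        return "core_satellite", trace
    trace["rule"] = "satellite peak, declining tail, no core mode"
    return "satellite_only", trace
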