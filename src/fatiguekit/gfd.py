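"""Global Fatigue Descriptor: CV-inverse-weighted fusion of normalized
individual fatigue descriptors, with three-zone staging.

    GFD[i] = sum_k IFD_k[i] / CV_k  /  sum_k 1 / CV_k

Each IFD series is first normalized by its calibration maximum so every
input (and hence the GFD) lives in [0, 1].  Zone thresholds are the 25%
percentile and the median of a calibration GFD distribution: green above
the median (innocuous), yellow between, red at or below the 25% percentile
(dangerous).
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .types import GFDProfile, IFDSpec, ParameterSeries

__all__ = [
    "normalize_ifd",
    "compute_gfd",
    "gfd_series",
    "align_series",
    "calibrate_thresholds",
    "cohort_thresholds",
    "zone",
]


def normalize_ifd(values: np.ndarray, max_value: float) -> np.ndarray:
    """``value / max_value`` clipped to [0, 1] (negatives clip to 0)."""
    if max_value <= 0:
        raise InvalidInputError("normalization maximum must be positive")
    return np.clip(np.asarray(values, dtype=float) / max_value, 0.0, 1.0)


def compute_gfd(ifd_samples: Sequence[float], specs: Sequence[IFDSpec]) -> float:
    """Weighted mean of normalized IFD samples with weights 1/CV_k."""
    if len(specs) == 0:
        raise InvalidInputError("at least one fatigue descriptor required")
    if len(ifd_samples) != len(specs):
        raise InvalidInputError("one sample per descriptor required")
    x = np.asarray(ifd_samples, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise InvalidInputError("normalized samples must lie in [0, 1]")
    w = np.array([1.0 / s.cv for s in specs])
    return float(np.sum(x * w) / np.sum(w))


def align_series(series: Mapping[str, ParameterSeries]) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Sample every descriptor series on a shared clock.

    The clock starts at the latest first-window time, ends at the earliest
    last-window time, and steps by the smallest step among the series;
    each series contributes its most recent (nearest-previous) window
    value at every tick.
    """
    if not series:
        raise InvalidInputError("no series to align")
    t_start = max(float(s.times[0]) for s in series.values())
    t_end = min(float(s.times[-1]) for s in series.values())
    if t_end < t_start:
        raise InvalidInputError("series do not overlap in time")
    step = min(float(np.min(np.diff(s.times))) if len(s) > 1 else np.inf
               for s in series.values())
    if not np.isfinite(step):
        step = max(t_end - t_start, 1.0)
    clock = np.arange(t_start, t_end + step / 2, step)
    aligned = {}
    for pid, s in series.items():
        idx = np.searchsorted(s.times, clock, side="right") - 1
        aligned[pid] = s.values[np.clip(idx, 0, len(s) - 1)]
    return clock, aligned


def gfd_series(series: Mapping[str, ParameterSeries],
               specs: Sequence[IFDSpec],
               invert_increasing: bool = False) -> ParameterSeries:
    """GFD over time from one participant's IFD series.

    Series are normalized by each spec's calibration maximum, aligned on a
    common clock, and fused.  ``invert_increasing`` maps descriptors whose
    fatigue trend is increasing through ``1 - x`` before fusion (off by
    default: the fusion tolerates a minority of increasing inputs).
    """
    spec_map = {s.param_id: s for s in specs}
    missing = [p for p in spec_map if p not in series]
    if missing:
        raise InvalidInputError(f"missing series for descriptors {missing}")
    clock, aligned = align_series({p: series[p] for p in spec_map})
    ordered = list(spec_map)
    rows = []
    for k, t in enumerate(clock):
        sample = []
        for p in ordered:
            x = float(normalize_ifd(aligned[p][k:k + 1], spec_map[p].max_value)[0])
            if invert_increasing and spec_map[p].direction == "increasing":
                x = 1.0 - x
            sample.append(x)
        rows.append(compute_gfd(sample, [spec_map[p] for p in ordered]))
    pid = next(iter(series.values())).participant_id
    return ParameterSeries(param_id="gfd", participant_id=pid, config=None,
                           times=clock, values=np.asarray(rows))


def calibrate_thresholds(gfd_values: np.ndarray) -> GFDProfile:
    """25% percentile and median of a calibration GFD distribution
    (linear interpolation between order statistics)."""
    x = np.asarray(gfd_values, dtype=float)
    if x.size < 10:
        raise InvalidInputError("calibration needs at least 10 GFD samples")
    q25, med = np.quantile(x, [0.25, 0.5])
    return GFDProfile(q25=float(q25), median=float(med))


def cohort_thresholds(profiles: Sequence[GFDProfile]) -> dict[str, float]:
    """Cohort-level thresholds: mean of per-participant thresholds with
    their standard deviation (error bars)."""
    if not profiles:
        raise InvalidInputError("no profiles")
    q = np.array([p.q25 for p in profiles])
    m = np.array([p.median for p in profiles])
    return {"q25_mean": float(q.mean()), "q25_sd": float(q.std()),
            "median_mean": float(m.mean()), "median_sd": float(m.std())}


def zone(gfd_value: float, profile: GFDProfile) -> str:
    """green if value > median; yellow if q25 < value <= median;
    red if value <= q25."""
    if gfd_value > profile.median:
        return "green"
    if gfd_value > profile.q25:
        return "yellow"
    return "red"
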