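"""Sliding-window extraction of descriptor evolution series.

EMG windows are counted in muscular activation periods: each activation is
analyzed individually and the per-activation values inside a window are
averaged into one sample.  HRV windows are spans of seconds over the
tachogram, with every descriptor recomputed on the RR intervals inside the
span.  The step between consecutive windows is a percentage of the window
size; 0% denotes non-overlapping windows (step = window size).
"""
from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import hrv
from .exceptions import InvalidInputError
from .types import EMG, ParameterSeries, Tachogram, WindowConfig

__all__ = [
    "EMG_WINDOW_SIZES",
    "HRV_WINDOW_SIZES",
    "TIME_STEPS_PERCENT",
    "window_grid",
    "window_starts",
    "extract_emg_series",
    "extract_hrv_series",
    "hrv_descriptor_table",
    "hrv_series_from_table",
    "extract_series",
    "count_series",
    "series_to_frame",
    "frame_to_series",
]

EMG_WINDOW_SIZES = (5, 10, 15, 20, 25)            # muscular activations
HRV_WINDOW_SIZES = tuple(range(30, 121, 10))      # seconds
TIME_STEPS_PERCENT = (0, 10, 25, 50, 75, 90)      # % of window size


def window_grid(modality: str) -> list[WindowConfig]:
    """All (window size, time step) configurations for one modality:
    5 x 6 = 30 for EMG, 10 x 6 = 60 for HRV."""
    sizes = EMG_WINDOW_SIZES if modality == EMG else HRV_WINDOW_SIZES
    return [WindowConfig(ws=float(ws), ts_percent=float(ts), modality=modality)
            for ws in sizes for ts in TIME_STEPS_PERCENT]


def window_starts(n_units: float, ws: float, step: float) -> np.ndarray:
    """Start offsets of every full window of size ``ws`` advancing by
    ``step`` over ``n_units`` (count or seconds)."""
    if ws > n_units:
        return np.array([])
    n_windows = int(np.floor((n_units - ws) / step)) + 1
    return np.arange(n_windows) * step


def extract_emg_series(
    activation_times: Sequence[float],
    values: Sequence[float],
    config: WindowConfig,
    param_id: str = "",
    participant_id: str = "",
) -> ParameterSeries:
    """Average per-activation descriptor values over windows of
    ``config.ws`` consecutive activations.

    ``activation_times`` are the activation centers in seconds; the window
    timestamp is the center of the spanned time range.
    """
    t = np.asarray(activation_times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size:
        raise InvalidInputError("times and values must match")
    ws = int(config.ws)
    step = int(config.step)
    starts = window_starts(t.size, ws, step).astype(int)
    times = np.array([(t[s] + t[s + ws - 1]) / 2.0 for s in starts])
    means = np.array([np.nanmean(v[s:s + ws]) for s in starts])
    return ParameterSeries(param_id=param_id, participant_id=participant_id,
                           config=config, times=times, values=means)


def extract_hrv_series(
    tachogram: Tachogram,
    config: WindowConfig,
    param_id: str,
    participant_id: str = "",
    resample_rate: float = 4.0,
) -> ParameterSeries:
    """Recompute one HRV descriptor on every ``config.ws``-second span.

    RR intervals are attributed to a window when their terminating beat
    falls inside the span.  Windows whose descriptor is undefined (too few
    beats, unresolvable band) are dropped from the series.
    """
    table = hrv_descriptor_table(tachogram, config,
                                 resample_rate=resample_rate)
    if table.empty:
        return ParameterSeries(param_id=param_id,
                               participant_id=participant_id, config=config,
                               times=np.array([]), values=np.array([]))
    return hrv_series_from_table(table, param_id, config,
                                 participant_id=participant_id)


def hrv_descriptor_table(
    tachogram: Tachogram,
    config: WindowConfig,
    resample_rate: float = 4.0,
) -> pd.DataFrame:
    """All HRV descriptors for every window in one pass.

    Returns a frame with a ``t`` column (window centers) and one column
    per descriptor; undefined values are NaN.
    """
    ws, step = config.ws, config.step
    t0 = float(tachogram.beat_times[0])
    starts = t0 + window_starts(tachogram.duration_s, ws, step)
    t_rr = tachogram.beat_times[1:]
    rows = []
    for s in starts:
        sel = (t_rr >= s) & (t_rr < s + ws)
        if sel.sum() < 4:
            continue
        try:
            d = hrv.window_descriptors(t_rr[sel], tachogram.rr[sel],
                                       window_span_s=ws,
                                       resample_rate=resample_rate)
        except InvalidInputError:
            continue
        d["t"] = s + ws / 2.0
        rows.append(d)
    return pd.DataFrame(rows)


def hrv_series_from_table(table: pd.DataFrame, param_id: str,
                          config: WindowConfig,
                          participant_id: str = "") -> ParameterSeries:
    """One descriptor column of :func:`hrv_descriptor_table` as a series
    (NaN windows dropped)."""
    sel = np.isfinite(table[param_id].to_numpy(dtype=float))
    return ParameterSeries(param_id=param_id, participant_id=participant_id,
                           config=config,
                           times=table["t"].to_numpy(dtype=float)[sel],
                           values=table[param_id].to_numpy(dtype=float)[sel])


def extract_series(data, param_id: str, config: WindowConfig,
                   participant_id: str = "", **kw) -> ParameterSeries:
    """Dispatch on modality: EMG takes ``(activation_times, values)``,
    HRV takes a :class:`Tachogram`."""
    if config.modality == EMG:
        activation_times, values = data
        return extract_emg_series(activation_times, values, config,
                                  param_id=param_id,
                                  participant_id=participant_id)
    return extract_hrv_series(data, config, param_id,
                              participant_id=participant_id, **kw)


def count_series(n_subjects_emg: int, n_emg_params: int, n_muscles: int,
                 n_subjects_hrv: int, n_hrv_params: int,
                 z_emg: int = len(EMG_WINDOW_SIZES),
                 z_hrv: int = len(HRV_WINDOW_SIZES),
                 y: int = len(TIME_STEPS_PERCENT)) -> int:
    """Total number of evolution series produced by the full grid."""
    return (n_subjects_emg * n_emg_params * n_muscles * z_emg * y
            + n_subjects_hrv * n_hrv_params * z_hrv * y)


def series_to_frame(series: Sequence[ParameterSeries]) -> pd.DataFrame:
    """Long-format store: one row per (participant, param, ws, ts, t)."""
    rows = []
    for s in series:
        for t, v in zip(s.times, s.values):
            rows.append({
                "participant": s.participant_id, "param": s.param_id,
                "modality": s.config.modality, "ws": s.config.ws,
                "ts_percent": s.config.ts_percent, "t": t, "value": v,
            })
    return pd.DataFrame(rows, columns=["participant", "param", "modality",
                                       "ws", "ts_percent", "t", "value"])


def frame_to_series(frame: pd.DataFrame) -> list[ParameterSeries]:
    """Inverse of :func:`series_to_frame` (round-trips configurations)."""
    out = []
    keys = ["participant", "param", "modality", "ws", "ts_percent"]
    for (pid, param, modality, ws, ts), grp in frame.groupby(keys, sort=False):
        grp = grp.sort_values("t")
        cfg = WindowConfig(ws=float(ws), ts_percent=float(ts),
                           modality=str(modality))
        out.append(ParameterSeries(param_id=param, participant_id=pid,
                                   config=cfg,
                                   times=grp["t"].to_numpy(),
                                   values=grp["value"].to_numpy()))
    return out
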