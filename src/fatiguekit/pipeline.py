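"""End-to-end orchestration: signals -> events -> descriptor series ->
trend meta-analysis -> IFD selection -> GFD -> classifier inputs.

These functions are thin compositions of the per-stage modules; every
stage remains usable on its own.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify, emg, events, gfd, hrv, meta, windows
from .exceptions import InvalidInputError
from .types import (EMG, CombinedTrend, IFDSpec, ParameterSeries,
                    SampledSignal, Tachogram, TrendDecision, WindowConfig)

__all__ = [
    "emg_descriptor_table",
    "emg_series",
    "hrv_series",
    "reference_config",
    "trial_ifd_series",
    "cohort_trend",
    "grid_trends",
    "best_config_trend",
    "ifd_decision",
    "ifd_specs_from_cohort",
    "participant_gfd",
]

#: descriptors that require the (costly) wavelet scalogram
WAVELET_PARAMS = frozenset({
    "emg_wavelet_median_frequency", "emg_major_frequency", "emg_major_time",
    "emg_mean_power", "emg_area", "emg_volume", "emg_time_dispersion",
    "emg_frequency_dispersion",
})


def emg_descriptor_table(
    signal: SampledSignal,
    params: Sequence[str] | None = None,
    scalogram_cfg: emg.ScalogramConfig | None = None,
    detector_kwargs: dict | None = None,
    segments=None,
) -> pd.DataFrame:
    """Detect activations and compute the requested descriptors per
    activation.  Returns a frame with ``center_s``, ``start_s``, ``end_s``
    and one column per descriptor; the scalogram is only computed when a
    wavelet descriptor is requested.
    """
    if params is None:
        params = emg.EMG_PARAM_IDS
    if segments is None:
        segments = events.detect_activations(signal, **(detector_kwargs or {}))
    need_wavelet = bool(set(params) & WAVELET_PARAMS)
    need_spectrum = bool({"emg_median_frequency", "emg_total_power"} & set(params))
    if scalogram_cfg is None and need_wavelet:
        scalogram_cfg = emg.ScalogramConfig(fs=signal.fs)
    rows = []
    for seg in segments:
        x = seg.slice(signal)
        row: dict[str, float] = {"center_s": seg.center_s,
                                 "start_s": seg.start / signal.fs,
                                 "end_s": seg.end / signal.fs}
        if "emg_rms" in params:
            row["emg_rms"] = emg.rms(x)
        if need_spectrum:
            spec = emg.power_spectrum(x, signal.fs)
            if "emg_median_frequency" in params:
                row["emg_median_frequency"] = emg.median_frequency(spec)
            if "emg_total_power" in params:
                row["emg_total_power"] = emg.total_power(spec)
        if need_wavelet:
            S = emg.compute_scalogram(x, scalogram_cfg)
            if "emg_wavelet_median_frequency" in params:
                row["emg_wavelet_median_frequency"] = emg.wavelet_median_frequency(S)
            if {"emg_major_time", "emg_major_frequency"} & set(params):
                mt, mf = emg.scalogram_centroid(S)
                row["emg_major_time"] = mt
                row["emg_major_frequency"] = mf
            if "emg_mean_power" in params:
                row["emg_mean_power"] = emg.mean_power(S)
            if {"emg_area", "emg_volume", "emg_time_dispersion",
                    "emg_frequency_dispersion"} & set(params):
                conv = emg.convex_descriptors(S, emg.otsu_mask(S))
                row["emg_area"] = conv.area
                row["emg_volume"] = conv.volume
                row["emg_time_dispersion"] = conv.time_dispersion
                row["emg_frequency_dispersion"] = conv.frequency_dispersion
        rows.append(row)
    return pd.DataFrame(rows)


def emg_series(table: pd.DataFrame, param_id: str, config: WindowConfig,
               participant_id: str = "") -> ParameterSeries:
    """Window-average one column of an activation descriptor table."""
    return windows.extract_emg_series(table["center_s"].to_numpy(),
                                      table[param_id].to_numpy(), config,
                                      param_id=param_id,
                                      participant_id=participant_id)


def hrv_series(tachogram: Tachogram, param_id: str, config: WindowConfig,
               participant_id: str = "") -> ParameterSeries:
    return windows.extract_hrv_series(tachogram, config, param_id,
                                      participant_id=participant_id)


def reference_config(param_id: str) -> WindowConfig:
    """WindowConfig for a descriptor's most favorable (ws, ts) pair from
    the bundled reference trend table."""
    from . import reference

    row = reference.reference_trend(param_id)
    ts_percent = 0.0 if row.ts == 0 else round(row.ts / row.ws * 100)
    return WindowConfig(ws=float(row.ws), ts_percent=float(ts_percent),
                        modality=row.modality)


def trial_ifd_series(
    emg_signal: SampledSignal | None,
    tachogram: Tachogram | None,
    participant_id: str = "",
    params: Sequence[str] | None = None,
    scalogram_cfg: emg.ScalogramConfig | None = None,
    detector_kwargs: dict | None = None,
) -> dict[str, ParameterSeries]:
    """All individual-fatigue-descriptor series of one trial, each at its
    reference window configuration.

    EMG descriptors come from one per-activation table (the activation
    analysis does not depend on the window configuration); HRV descriptors
    from one per-window table per distinct configuration.
    """
    from . import reference

    if params is None:
        params = [r.param_id for r in reference.REFERENCE_TRENDS]
    emg_params = [p for p in params if p.startswith("emg_")]
    hrv_params = [p for p in params if p.startswith("hrv_")]
    out: dict[str, ParameterSeries] = {}
    if emg_params:
        if emg_signal is None:
            raise InvalidInputError("EMG descriptors requested without a signal")
        table = emg_descriptor_table(emg_signal, params=emg_params,
                                     scalogram_cfg=scalogram_cfg,
                                     detector_kwargs=detector_kwargs)
        for p in emg_params:
            out[p] = emg_series(table, p, reference_config(p),
                                participant_id=participant_id)
    if hrv_params:
        if tachogram is None:
            raise InvalidInputError("HRV descriptors requested without a tachogram")
        by_cfg: dict[WindowConfig, list[str]] = {}
        for p in hrv_params:
            by_cfg.setdefault(reference_config(p), []).append(p)
        for cfg, plist in by_cfg.items():
            table = windows.hrv_descriptor_table(tachogram, cfg)
            for p in plist:
                out[p] = windows.hrv_series_from_table(
                    table, p, cfg, participant_id=participant_id)
    return out


def cohort_trend(series: Sequence[ParameterSeries],
                 alpha: float = 0.05) -> CombinedTrend:
    """Fit per-participant slopes and pool them into a combined trend."""
    results = [meta.fit_slope(s) for s in series if len(s) >= 3]
    if not results:
        raise InvalidInputError("no participant series long enough to fit")
    return meta.combined_trend(results, alpha=alpha)


def grid_trends(
    extract,  # (config) -> list[ParameterSeries], one per participant
    configs: Sequence[WindowConfig],
) -> dict[WindowConfig, CombinedTrend]:
    """Combined trend under every window configuration; configurations
    where pooling fails (too few windows, zero slope) are skipped."""
    from .exceptions import UndefinedResultError

    out: dict[WindowConfig, CombinedTrend] = {}
    for cfg in configs:
        try:
            out[cfg] = cohort_trend(extract(cfg))
        except (InvalidInputError, UndefinedResultError):
            continue
    return out


def best_config_trend(trends: Mapping[WindowConfig, CombinedTrend]):
    return meta.select_best_config(trends)


def ifd_decision(trend_plus: CombinedTrend,
                 trend_minus: CombinedTrend) -> TrendDecision:
    return meta.trend_criteria(trend_plus, trend_minus)


def ifd_specs_from_cohort(
    cohort_series: Mapping[str, Mapping[str, ParameterSeries]],
    trends: Mapping[str, CombinedTrend],
) -> list[IFDSpec]:
    """Build IFD fusion specs: CV from the pooled trend, normalization
    maximum as the cohort-wide maximum of each descriptor series."""
    specs = []
    for param, trend in trends.items():
        if trend.cv is None:
            continue
        vals = np.concatenate([np.asarray(per[param].values)
                               for per in cohort_series.values()
                               if param in per])
        mx = float(np.nanmax(vals))
        if mx <= 0:
            continue
        direction = "increasing" if trend.m_comb > 0 else "decreasing"
        specs.append(IFDSpec(param_id=param, cv=float(trend.cv),
                             max_value=mx, direction=direction))
    return specs


def participant_gfd(per_param: Mapping[str, ParameterSeries],
                    specs: Sequence[IFDSpec]) -> ParameterSeries:
    return gfd.gfd_series(per_param, specs)
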