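"""HRV descriptors per RR-interval window.

Time domain: max/min/mean RR, SDNN, rmsSD, triangular index, Poincaré
SD1/SD2.  Frequency domain: band powers (ULF/VLF/LF/HF) and median
frequency of the RR spectrum, computed on an evenly resampled tachogram.

Variance convention is population (1/n) by default; switch with
``ddof=1`` where exposed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .emg import Spectrum, median_frequency
from .exceptions import InvalidInputError

__all__ = [
    "BANDS",
    "PoincareResult",
    "rr_time_stats",
    "triangular_index",
    "poincare",
    "rr_spectrum",
    "band_power",
    "hrv_median_frequency",
    "window_descriptors",
    "HRV_PARAM_IDS",
]

#: standard HRV bands, Hz.  Half-open [lo, hi) except HF which is closed.
BANDS: dict[str, tuple[float, float]] = {
    "ULF": (0.0, 0.003),
    "VLF": (0.003, 0.040),
    "LF": (0.040, 0.150),
    "HF": (0.150, 0.400),
}

HRV_PARAM_IDS = [
    "hrv_max_rr",
    "hrv_min_rr",
    "hrv_mean_rr",
    "hrv_sdnn",
    "hrv_rmssd",
    "hrv_triangular_index",
    "hrv_sd1",
    "hrv_sd2",
    "hrv_sd1_sd2",
    "hrv_power_ulf",
    "hrv_power_vlf",
    "hrv_power_lf",
    "hrv_power_hf",
    "hrv_median_frequency",
]


@dataclass
class PoincareResult:
    sd1: float
    sd2: float

    @property
    def ratio(self) -> float:
        return self.sd1 / self.sd2 if self.sd2 > 0 else np.nan


def rr_time_stats(rr: np.ndarray, ddof: int = 0) -> dict[str, float]:
    """max, min, mean, SDNN and rmsSD of an RR window (seconds)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        raise InvalidInputError("need at least 2 RR intervals")
    diffs = np.diff(rr)
    return {
        "max": float(rr.max()),
        "min": float(rr.min()),
        "mean": float(rr.mean()),
        "sdnn": float(rr.std(ddof=ddof)),
        "rmssd": float(np.sqrt(np.mean(diffs ** 2))),
    }


def triangular_index(rr: np.ndarray, bin_width: float = 1.0 / 128.0) -> float:
    """Number of intervals divided by the modal histogram-bin count.

    The 1/128 s bin width follows the clinical HRV convention.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size == 0:
        raise InvalidInputError("empty RR window")
    lo = np.floor(rr.min() / bin_width) * bin_width
    hi = np.ceil(rr.max() / bin_width) * bin_width
    nbins = max(1, int(round((hi - lo) / bin_width)))
    counts, _ = np.histogram(rr, bins=nbins, range=(lo, lo + nbins * bin_width))
    return float(rr.size / counts.max())


def poincare(rr: np.ndarray, ddof: int = 0) -> PoincareResult:
    """Poincaré SD1/SD2 from the lag-1 scatter rotated 45 degrees.

    SD1 is the dispersion perpendicular to the line of identity and SD2
    along it; equivalently SD1^2 = var(diff)/2 and
    SD2^2 = 2 var(rr) - var(diff)/2 with plug-in variances.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 3:
        raise InvalidInputError("need at least 3 RR intervals for Poincare")
    a, b = rr[:-1], rr[1:]
    perp = (b - a) / np.sqrt(2.0)
    along = (a + b) / np.sqrt(2.0)
    return PoincareResult(sd1=float(perp.std(ddof=ddof)),
                          sd2=float(along.std(ddof=ddof)))


def rr_spectrum(beat_times: np.ndarray, rr: np.ndarray,
                resample_rate: float = 4.0) -> Spectrum:
    """Power spectral density of the RR series in s^2/Hz.

    The tachogram, an unevenly sampled series (one RR value at each beat
    time), is cubic-spline resampled at ``resample_rate``, linearly
    detrended, and passed through a periodogram.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    rr = np.asarray(rr, dtype=float)
    if rr.size < 4:
        raise InvalidInputError("need at least 4 RR intervals for a spectrum")
    # attribute each interval to the time of its terminating beat; accept
    # either the full beat-time vector or per-interval times directly
    t_rr = beat_times[1:] if beat_times.size == rr.size + 1 else beat_times
    cs = CubicSpline(t_rr, rr)
    t_even = np.arange(t_rr[0], t_rr[-1], 1.0 / resample_rate)
    if t_even.size < 8:
        raise InvalidInputError("window too short for spectral analysis")
    x = cs(t_even)
    freqs, power = sps.periodogram(x, fs=resample_rate, detrend="linear")
    return Spectrum(freqs=freqs, power=power)


def band_power(spec: Spectrum, band: tuple[float, float],
               closed_right: bool = False) -> float:
    """Trapezoid-integrated power inside ``band`` = (lo, hi).

    Bands are half-open [lo, hi) so adjacent bands never double-count a
    shared edge; pass ``closed_right=True`` for the last band (HF).
    """
    lo, hi = band
    f, p = spec.freqs, spec.power
    if closed_right:
        sel = (f >= lo) & (f <= hi)
    else:
        sel = (f >= lo) & (f < hi)
    if sel.sum() < 2:
        return float(p[sel].sum()) if sel.any() else 0.0
    return float(np.trapezoid(p[sel], f[sel]))


def resolvable(band: tuple[float, float], window_span_s: float) -> bool:
    """A band is resolvable when the window holds at least one full period
    of the band's lower edge (so LF needs 25 s, VLF 333 s); a band starting
    at 0 Hz (ULF) is never resolvable on windows of minutes or less."""
    lo = band[0]
    if lo <= 0:
        return False
    return window_span_s >= 1.0 / lo


def hrv_median_frequency(spec: Spectrum,
                         band: tuple[float, float] = (0.003, 0.4)) -> float:
    """Cumulative-half median frequency over the analyzed HRV band.

    ULF is excluded by default because windows of a few minutes or less
    cannot resolve it.
    """
    sel = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    return median_frequency(Spectrum(freqs=spec.freqs[sel], power=spec.power[sel]))


def window_descriptors(beat_times: np.ndarray, rr: np.ndarray,
                       window_span_s: float | None = None,
                       resample_rate: float = 4.0,
                       ddof: int = 0) -> dict[str, float]:
    """All HRV descriptors of one RR window as a flat dict.

    Band powers whose band cannot be resolved in ``window_span_s`` are
    reported as NaN (undefined), not as a number.
    """
    rr = np.asarray(rr, dtype=float)
    if window_span_s is None:
        window_span_s = float(beat_times[-1] - beat_times[0]) if len(beat_times) else 0.0
    stats = rr_time_stats(rr, ddof=ddof)
    pc = poincare(rr, ddof=ddof)
    out = {
        "hrv_max_rr": stats["max"],
        "hrv_min_rr": stats["min"],
        "hrv_mean_rr": stats["mean"],
        "hrv_sdnn": stats["sdnn"],
        "hrv_rmssd": stats["rmssd"],
        "hrv_triangular_index": triangular_index(rr),
        "hrv_sd1": pc.sd1,
        "hrv_sd2": pc.sd2,
        "hrv_sd1_sd2": pc.ratio,
    }
    try:
        spec = rr_spectrum(beat_times, rr, resample_rate=resample_rate)
    except InvalidInputError:
        spec = None
    band_keys = {"ULF": "hrv_power_ulf", "VLF": "hrv_power_vlf",
                 "LF": "hrv_power_lf", "HF": "hrv_power_hf"}
    for name, key in band_keys.items():
        band = BANDS[name]
        if spec is None or not resolvable(band, window_span_s):
            out[key] = np.nan
        else:
            out[key] = band_power(spec, band, closed_right=(name == "HF"))
    if spec is not None:
        try:
            out["hrv_median_frequency"] = hrv_median_frequency(spec)
        except Exception:
            out["hrv_median_frequency"] = np.nan
    else:
        out["hrv_median_frequency"] = np.nan
    return out
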