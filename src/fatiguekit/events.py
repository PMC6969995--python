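"""Event detection: EMG muscular activation periods and ECG R-peaks.

EMG activations are found with a Teager–Kaiser Energy Operator (TKEO)
envelope and an adaptive baseline threshold; R-peaks with the classic
Pan–Tompkins chain (band-pass, derivative, squaring, moving-window
integration, adaptive dual thresholds with search-back).
"""
from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .exceptions import InvalidInputError
from .types import ECG, EMG, ActivationSegment, SampledSignal, Tachogram

__all__ = [
    "tkeo",
    "detect_activations",
    "detect_r_peaks",
    "build_tachogram",
]


def tkeo(signal: SampledSignal) -> SampledSignal:
    """Teager–Kaiser Energy Operator, ``y[n] = x[n]^2 - x[n-1] x[n+1]``.

    Endpoints are set to 0 so the output has the same length as the input.
    For a pure sinusoid ``A sin(Ω n)`` the interior output is the constant
    ``A^2 sin^2(Ω)``, which is what makes the operator a cheap instantaneous
    energy tracker for burst detection.
    """
    x = signal.values
    if x.size < 3:
        raise InvalidInputError("TKEO needs at least 3 samples")
    y = np.zeros_like(x)
    y[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    return SampledSignal(y, signal.fs, kind=signal.kind,
                         channel_label=signal.channel_label)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    width = max(1, int(width))
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def detect_activations(
    emg: SampledSignal,
    smooth_window_s: float = 0.05,
    threshold_factor: float = 3.0,
    min_duration_s: float = 0.2,
    merge_gap_s: float = 0.1,
    baseline_s: float = 0.25,
) -> list[ActivationSegment]:
    """Detect muscular activation periods in a raw EMG recording.

    The TKEO output is full-wave rectified, smoothed with a moving average
    of ``smooth_window_s``, and thresholded at ``baseline mean +
    threshold_factor * baseline SD``.  The baseline is the quieter of (a)
    the first ``baseline_s`` of the record and (b) the quietest decile of
    the envelope, so a recording that starts mid-burst still yields a sane
    threshold.  Super-threshold runs closer than ``merge_gap_s`` are merged
    and runs shorter than ``min_duration_s`` discarded.

    Returns an ordered, non-overlapping list of segments (possibly empty).
    """
    if emg.kind != EMG:
        raise InvalidInputError(f"expected an EMG signal, got kind={emg.kind!r}")
    fs = emg.fs
    env = _moving_average(np.abs(tkeo(emg).values), round(smooth_window_s * fs))

    head = env[: max(2, round(baseline_s * fs))]
    decile = np.sort(env)[: max(2, env.size // 10)]
    # the head is the baseline unless the recording starts mid-burst, in
    # which case the quietest decile stands in (its SD is tail-truncated,
    # so it is only a fallback)
    baseline = head if head.mean() <= 3 * decile.mean() else decile
    thr = baseline.mean() + threshold_factor * baseline.std()

    above = env > thr
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])

    # drop isolated noise exceedances (shorter than the envelope smoothing
    # width) before gap-merging, so they cannot chain quiet spans together
    pre_min = 2 * smooth_window_s * fs
    keep = (run_ends - run_starts) >= pre_min
    run_starts, run_ends = run_starts[keep], run_ends[keep]

    # merge runs separated by short gaps
    merged: list[list[int]] = []
    gap = merge_gap_s * fs
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])

    min_len = min_duration_s * fs
    return [ActivationSegment(s, e, fs) for s, e in merged if e - s >= min_len]


def detect_r_peaks(
    ecg: SampledSignal,
    refractory_s: float = 0.2,
    integration_window_s: float = 0.15,
    searchback_factor: float = 1.66,
    relocate_window_s: float = 0.05,
) -> np.ndarray:
    """Pan–Tompkins QRS detection; returns ascending R-peak sample indices.

    Chain: 5–15 Hz band-pass -> five-point derivative -> squaring ->
    moving-window integration (``integration_window_s``) -> adaptive dual
    thresholds updated from running signal/noise peak estimates, with a
    ``refractory_s`` blanking period and a search-back pass at
    ``searchback_factor`` times the running RR mean.  Each accepted peak is
    finally relocated to the maximum of the raw signal within
    ``relocate_window_s`` of the integrated-signal peak.
    """
    if ecg.kind != ECG:
        raise InvalidInputError(f"expected an ECG signal, got kind={ecg.kind!r}")
    fs = ecg.fs
    if not (100 <= fs <= 2000):
        raise InvalidInputError("R-peak detection supports fs in [100, 2000] Hz")
    x = ecg.values
    win = round(integration_window_s * fs)
    if x.size <= win:
        raise InvalidInputError("record shorter than the integration window")

    sos = sps.butter(2, [5, 15], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(filt)
    squared = deriv ** 2
    integ = _moving_average(squared, win)

    if np.ptp(integ) == 0:
        return np.array([], dtype=int)

    # candidate local maxima of the integrated signal
    refr = round(refractory_s * fs)
    cand, _ = sps.find_peaks(integ, distance=max(1, refr))
    if cand.size == 0:
        return np.array([], dtype=int)

    # adaptive thresholds (Pan-Tompkins running estimates)
    warm = int(2 * fs)
    head = integ[:warm] if integ.size >= warm else integ
    spki = float(np.max(head)) * 0.5
    npki = float(np.mean(head)) * 0.5
    peaks: list[int] = []
    rr_recent: list[float] = []

    def threshold1() -> float:
        return npki + 0.25 * (spki - npki)

    for c in cand:
        pk = float(integ[c])
        if pk > threshold1():
            if peaks and (c - peaks[-1]) < refr:
                continue
            peaks.append(int(c))
            spki = 0.125 * pk + 0.875 * spki
            if len(peaks) >= 2:
                rr_recent.append(peaks[-1] - peaks[-2])
                rr_recent = rr_recent[-8:]
        else:
            npki = 0.125 * pk + 0.875 * npki
        # search-back: missed beat if the gap exceeds searchback_factor * mean RR
        if len(rr_recent) >= 2 and peaks:
            rr_mean = float(np.mean(rr_recent))
            if (c - peaks[-1]) > searchback_factor * rr_mean:
                seg = cand[(cand > peaks[-1] + refr) & (cand < c)]
                if seg.size:
                    best = seg[np.argmax(integ[seg])]
                    if integ[best] > 0.5 * threshold1():
                        peaks.append(int(best))
                        peaks.sort()
                        spki = 0.25 * float(integ[best]) + 0.75 * spki

    if not peaks:
        return np.array([], dtype=int)

    # relocate each detection to the raw-signal maximum nearby
    half = round(relocate_window_s * fs)
    out = []
    for p in sorted(set(peaks)):
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        out.append(lo + int(np.argmax(x[lo:hi])))
    out = np.asarray(sorted(set(out)), dtype=int)
    # enforce refractory period after relocation
    keep = [0]
    for i in range(1, out.size):
        if out[i] - out[keep[-1]] >= refr:
            keep.append(i)
    return out[keep]


def build_tachogram(peaks: np.ndarray, fs: float) -> Tachogram:
    """Convert R-peak sample indices into a tachogram (beat times + RR)."""
    peaks = np.asarray(peaks)
    if peaks.size < 2:
        raise InvalidInputError("need at least 2 peaks to build a tachogram")
    if np.any(np.diff(peaks) <= 0):
        raise InvalidInputError("peak indices must be strictly ascending")
    beat_times = peaks / fs
    return Tachogram(beat_times=beat_times, rr=np.diff(beat_times))
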