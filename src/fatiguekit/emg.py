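"""EMG descriptors per muscular activation period.

Time domain: RMS.  Frequency domain: periodogram median frequency and
total power.  Time-frequency domain: complex-Morlet scalogram descriptors
(median frequency, Major Time / Major Frequency centroid, mean power, and
Otsu-segmented convex-hull descriptors: area, volume, time dispersion,
frequency dispersion).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps
from scipy.spatial import ConvexHull, QhullError
from skimage.filters import threshold_otsu

from .exceptions import DegenerateInputError, InvalidInputError, UndefinedResultError

__all__ = [
    "Spectrum",
    "ScalogramConfig",
    "Scalogram",
    "ConvexDescriptors",
    "rms",
    "power_spectrum",
    "median_frequency",
    "total_power",
    "morlet_scales",
    "compute_scalogram",
    "scalogram_centroid",
    "mean_power",
    "otsu_mask",
    "convex_descriptors",
    "wavelet_median_frequency",
    "activation_descriptors",
    "EMG_PARAM_IDS",
]

#: canonical Morlet center frequency that reproduces the standard
#: pseudofrequency <-> scale conversion scale = fc * fs / f
MORLET_FC = 0.8125

EMG_PARAM_IDS = [
    "emg_rms",
    "emg_median_frequency",
    "emg_total_power",
    "emg_wavelet_median_frequency",
    "emg_major_frequency",
    "emg_major_time",
    "emg_mean_power",
    "emg_area",
    "emg_volume",
    "emg_time_dispersion",
    "emg_frequency_dispersion",
]


@dataclass
class Spectrum:
    """One-sided power spectrum on an ascending frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.size != self.power.size:
            raise InvalidInputError("freqs and power must match in length")
        if np.any(np.diff(self.freqs) <= 0):
            raise InvalidInputError("frequency grid must be ascending")
        if np.any(self.power < 0):
            raise InvalidInputError("power must be nonnegative")


@dataclass
class ScalogramConfig:
    """Morlet scalogram settings.

    ``pseudofreqs`` defaults to 5, 7, ..., 499 Hz (2 Hz spacing over the
    informative surface-EMG band); ``fc`` is the Morlet center frequency
    and ``b`` its bandwidth parameter.
    """

    fs: float = 1000.0
    fc: float = MORLET_FC
    b: float = 2.0
    pseudofreqs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pseudofreqs is None:
            self.pseudofreqs = np.arange(5.0, 500.0, 2.0)
        self.pseudofreqs = np.asarray(self.pseudofreqs, dtype=float)
        if self.fc <= 0:
            raise InvalidInputError("fc must be positive")
        if np.any(self.pseudofreqs <= 0) or np.any(self.pseudofreqs >= self.fs / 2):
            raise InvalidInputError("pseudofrequencies must lie in (0, fs/2)")
        if np.any(np.diff(self.pseudofreqs) <= 0):
            raise InvalidInputError("pseudofrequencies must be ascending")

    @property
    def wavelet_name(self) -> str:
        return f"cmor{self.b:g}-{self.fc:g}"


@dataclass
class Scalogram:
    """|CWT| magnitude map: rows = ascending pseudofrequency, cols = time."""

    S: np.ndarray
    time_axis: np.ndarray
    freq_axis: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (self.freq_axis.size, self.time_axis.size):
            raise InvalidInputError("scalogram shape must be (F, T)")

    @property
    def dt(self) -> float:
        return float(self.time_axis[1] - self.time_axis[0]) if self.time_axis.size > 1 else 1.0

    @property
    def df(self) -> float:
        return float(self.freq_axis[1] - self.freq_axis[0]) if self.freq_axis.size > 1 else 1.0


@dataclass
class ConvexDescriptors:
    area: float
    volume: float
    time_dispersion: float
    frequency_dispersion: float


def rms(segment: np.ndarray) -> float:
    """Root mean square of a segment."""
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise InvalidInputError("RMS of an empty segment")
    return float(np.sqrt(np.mean(x ** 2)))


def power_spectrum(segment: np.ndarray, fs: float) -> Spectrum:
    """One-sided periodogram of the linearly detrended segment.

    A single ~1 s activation is short enough to be treated as stationary,
    so no Welch averaging is applied within it (configurable upstream by
    slicing the segment).
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 8:
        raise InvalidInputError("need at least 8 samples for a spectrum")
    freqs, power = sps.periodogram(x, fs=fs, detrend="linear")
    return Spectrum(freqs=freqs, power=power)


def median_frequency(spec: Spectrum) -> float:
    """Frequency splitting the spectrum into halves of equal power.

    Returns the smallest grid frequency whose cumulative power reaches
    half of the total.  When the half level is hit exactly (an even split,
    e.g. two equal lines at 50 and 150 Hz), the tie is resolved to the
    midpoint of the plateau — 100 Hz in that example — by linear
    interpolation between the two frequencies that bracket it.
    """
    p = spec.power
    total = p.sum()
    if total <= 0:
        raise UndefinedResultError("median frequency of a zero-power spectrum")
    cum = np.cumsum(p)
    half = total / 2.0
    k = int(np.searchsorted(cum, half))
    f_lo = float(spec.freqs[k])
    if abs(cum[k] - half) <= 1e-12 * total and k + 1 < cum.size:
        # exact even split: interpolate halfway to where mass resumes
        nxt = k + int(np.argmax(cum[k:] > cum[k] * (1 + 1e-12)))
        if cum[nxt] > cum[k]:
            return (f_lo + float(spec.freqs[nxt])) / 2.0
    return f_lo


def total_power(spec: Spectrum) -> float:
    """Total spectral power (sum over the analyzed band)."""
    return float(spec.power.sum())


def morlet_scales(cfg: ScalogramConfig) -> np.ndarray:
    """Wavelet scales for the configured pseudofrequencies.

    ``scale(f) = fc * fs / f``: with the standard Morlet center frequency
    fc = 0.8125 Hz at fs = 1000 Hz this maps 5 Hz -> 162.5, 7 Hz -> 116.071,
    9 Hz -> 90.278 and 499 Hz -> 1.628.
    """
    f = cfg.pseudofreqs
    if np.any(f <= 0):
        raise InvalidInputError("pseudofrequencies must be positive")
    return cfg.fc * cfg.fs / f


def compute_scalogram(segment: np.ndarray, cfg: ScalogramConfig) -> Scalogram:
    """Complex-Morlet CWT magnitude on the configured pseudofrequency grid.

    Rows are ordered by ascending pseudofrequency; the time axis keeps the
    native resolution 1/fs.
    """
    x = np.asarray(segment, dtype=float)
    if x.size == 0:
        raise InvalidInputError("empty segment")
    scales = morlet_scales(cfg)
    # pywt expects scales in samples; large scale = low frequency, so flip
    # to ascending-frequency row order afterwards.
    coeffs, _ = pywt.cwt(x, scales, cfg.wavelet_name,
                         sampling_period=1.0 / cfg.fs, method="fft")
    S = np.abs(coeffs)
    return Scalogram(S=S, time_axis=np.arange(x.size) / cfg.fs,
                     freq_axis=cfg.pseudofreqs.copy())


def scalogram_centroid(S: Scalogram, normalization: str = "intensity") -> tuple[float, float]:
    """(Major Time, Major Frequency) of a scalogram.

    ``intensity`` (default): magnitude-weighted centroid, i.e. the double
    sums divided by the total magnitude.  ``literal``: divided by T*F, the
    raw pixel count, which makes the result scale with image intensity and
    size; retained because some descriptor definitions use it verbatim.
    """
    M = S.S
    t = S.time_axis
    f = S.freq_axis
    wt = M.sum(axis=0)  # per-column mass
    wf = M.sum(axis=1)  # per-row mass
    num_t = float(np.dot(t, wt))
    num_f = float(np.dot(f, wf))
    if normalization == "literal":
        denom = M.size
        return num_t / denom, num_f / denom
    if normalization == "intensity":
        total = float(M.sum())
        if total <= 0:
            raise UndefinedResultError("centroid of an all-zero scalogram")
        return num_t / total, num_f / total
    raise InvalidInputError(f"unknown normalization {normalization!r}")


def mean_power(S: Scalogram) -> float:
    """Average of the scalogram entries."""
    return float(S.S.mean())


def otsu_mask(S: Scalogram, levels: int = 256) -> np.ndarray:
    """Binary mask keeping scalogram pixels at or above the Otsu threshold.

    Magnitudes are min-max scaled onto ``levels`` gray levels before the
    between-class-variance search, the reference convention for Otsu on
    continuous-valued images.
    """
    M = S.S
    lo, hi = float(M.min()), float(M.max())
    if hi == lo:
        raise DegenerateInputError("Otsu threshold of a constant scalogram")
    quant = np.round((M - lo) / (hi - lo) * (levels - 1)).astype(np.uint16)
    thr_q = threshold_otsu(quant, nbins=levels)
    # skimage convention: the threshold is the top of the background class,
    # so the retained (high-intensity) region is strictly above it
    mask = quant > thr_q
    if not mask.any():
        mask = quant >= quant.max()
    return mask


def convex_descriptors(S: Scalogram, mask: np.ndarray) -> ConvexDescriptors:
    """Convex-hull descriptors of the segmented scalogram region.

    The hull is taken over the (time, frequency) coordinates of the true
    pixels; area is in s*Hz, dispersions are the hull extents along each
    axis, and volume sums the magnitudes of all pixels inside the hull.
    Fewer than 3 non-collinear points degrade gracefully: area 0,
    dispersions = bounding extents, volume = masked-pixel sum.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return ConvexDescriptors(0.0, 0.0, 0.0, 0.0)
    t = S.time_axis[cols]
    f = S.freq_axis[rows]
    masked_sum = float(S.S[rows, cols].sum())
    if rows.size < 3:
        return ConvexDescriptors(0.0, masked_sum,
                                 float(np.ptp(t)), float(np.ptp(f)))
    pts = np.column_stack([t, f])
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear points
        return ConvexDescriptors(0.0, masked_sum,
                                 float(np.ptp(t)), float(np.ptp(f)))
    area = float(hull.volume)  # 2-D: .volume is the area
    inside = _pixels_in_hull(S, hull)
    volume = float(S.S[inside].sum())
    hp = pts[hull.vertices]
    return ConvexDescriptors(area, volume,
                             float(np.ptp(hp[:, 0])), float(np.ptp(hp[:, 1])))


def _pixels_in_hull(S: Scalogram, hull: ConvexHull) -> np.ndarray:
    """Boolean (F, T) map of pixel centers inside (or on) the hull."""
    T, F = np.meshgrid(S.time_axis, S.freq_axis)
    pts = np.column_stack([T.ravel(), F.ravel()])
    # hull.equations: A x + b <= 0 inside
    ok = np.all(pts @ hull.equations[:, :2].T + hull.equations[:, 2]
                <= 1e-12, axis=1)
    return ok.reshape(S.S.shape)


def wavelet_median_frequency(S: Scalogram) -> float:
    """Median frequency of the scalogram's marginal power over frequency.

    Each row's magnitudes are summed over time; the cumulative-half rule of
    :func:`median_frequency` is then applied to that marginal.
    """
    marginal = S.S.sum(axis=1)
    return median_frequency(Spectrum(freqs=S.freq_axis, power=marginal))


def activation_descriptors(segment: np.ndarray, fs: float,
                           cfg: ScalogramConfig | None = None,
                           centroid_normalization: str = "intensity") -> dict[str, float]:
    """All EMG descriptors of one activation period as a flat dict."""
    if cfg is None:
        cfg = ScalogramConfig(fs=fs)
    out: dict[str, float] = {"emg_rms": rms(segment)}
    spec = power_spectrum(segment, fs)
    out["emg_median_frequency"] = median_frequency(spec)
    out["emg_total_power"] = total_power(spec)
    S = compute_scalogram(segment, cfg)
    out["emg_wavelet_median_frequency"] = wavelet_median_frequency(S)
    mt, mf = scalogram_centroid(S, normalization=centroid_normalization)
    out["emg_major_time"] = mt
    out["emg_major_frequency"] = mf
    out["emg_mean_power"] = mean_power(S)
    mask = otsu_mask(S)
    conv = convex_descriptors(S, mask)
    out["emg_area"] = conv.area
    out["emg_volume"] = conv.volume
    out["emg_time_dispersion"] = conv.time_dispersion
    out["emg_frequency_dispersion"] = conv.frequency_dispersion
    return out
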