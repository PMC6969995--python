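"""Core containers for signals, events and analysis results.

All time quantities are seconds, frequencies Hz, RR intervals seconds
(millisecond input is converted at the I/O boundary).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import InvalidInputError

EMG = "EMG"
ECG = "ECG"


@dataclass
class SampledSignal:
    """A uniformly sampled waveform.

    Parameters
    ----------
    values : array-like
        Signal samples (e.g. mV).
    fs : float
        Sampling rate in Hz, > 0.
    kind : {"EMG", "ECG"}
        Modality tag used for precondition checks downstream.
    channel_label : str
        Free-text channel name (e.g. muscle).
    """

    values: np.ndarray
    fs: float
    kind: str = EMG
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        if self.values.ndim != 1 or self.values.size < 2:
            raise InvalidInputError("signal must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("signal contains non-finite samples")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs


@dataclass(frozen=True)
class ActivationSegment:
    """One muscular activation period, [start, end) in sample indices."""

    start: int
    end: int
    fs: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidInputError(f"bad segment bounds [{self.start}, {self.end})")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) / self.fs

    @property
    def center_s(self) -> float:
        return (self.start + self.end) / 2.0 / self.fs

    def slice(self, signal: SampledSignal) -> np.ndarray:
        return signal.values[self.start:self.end]


@dataclass
class Tachogram:
    """Beat times (s, ascending) and the RR intervals between them (s)."""

    beat_times: np.ndarray
    rr: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.rr is None:
            self.rr = np.diff(self.beat_times)
        else:
            self.rr = np.asarray(self.rr, dtype=float)
        if self.beat_times.size < 2:
            raise InvalidInputError("tachogram needs at least 2 beats")
        if self.rr.size != self.beat_times.size - 1:
            raise InvalidInputError("rr length must be number of beats - 1")
        if np.any(self.rr <= 0):
            raise InvalidInputError("RR intervals must be positive")

    @classmethod
    def from_rr(cls, rr: Sequence[float], t0: float = 0.0) -> "Tachogram":
        rr = np.asarray(rr, dtype=float)
        beats = t0 + np.concatenate([[0.0], np.cumsum(rr)])
        return cls(beat_times=beats, rr=rr)

    @property
    def duration_s(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])


@dataclass(frozen=True)
class WindowConfig:
    """One sliding-window configuration.

    ``ws`` is a count of activations for EMG, a span in seconds for HRV.
    ``ts_percent`` in {0, 10, 25, 50, 75, 90}: the step as a percentage of
    the window size; 0 denotes non-overlapping windows (step = ws).
    """

    ws: float
    ts_percent: float
    modality: str  # EMG | HRV

    @property
    def step(self) -> float:
        """Effective step in window units (activations or seconds)."""
        if self.ts_percent == 0:
            return float(self.ws)
        raw = self.ts_percent * self.ws / 100.0
        if self.modality == EMG:
            # whole activations, half-up rounding, at least one
            return float(max(1, int(np.floor(raw + 0.5))))
        return float(raw)

    @property
    def label(self) -> str:
        return f"{self.modality}_ws{self.ws:g}_ts{self.ts_percent:g}"


@dataclass
class ParameterSeries:
    """Evolution time series of one descriptor under one window configuration."""

    param_id: str
    participant_id: str
    config: WindowConfig | None
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise InvalidInputError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise InvalidInputError("series times must be strictly ascending")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class RegressionResult:
    """OLS slope and its sampling variance for one participant's series."""

    slope: float
    var_slope: float
    n_points: int
    intercept: float = 0.0


@dataclass
class CombinedTrend:
    """Fixed-effect inverse-variance combination of per-participant slopes."""

    m_comb: float
    var_comb: float
    n_subjects: int
    ci: tuple[float, float] | None = None
    cv: float | None = None

    @property
    def sd_comb(self) -> float:
        return float(np.sqrt(self.var_comb))


@dataclass
class TrendDecision:
    """Outcome of the two-stage fatigue-trend acceptability test."""

    has_trend_plus: bool
    reversal_or_uncertain_minus: bool
    direction: str  # increasing | decreasing

    @property
    def is_ifd(self) -> bool:
        return self.has_trend_plus and self.reversal_or_uncertain_minus


@dataclass
class IFDSpec:
    """One individual fatigue descriptor entering the global fusion."""

    param_id: str
    cv: float
    max_value: float
    direction: str = "decreasing"

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise InvalidInputError("IFD weight requires cv > 0")
        if self.max_value <= 0:
            raise InvalidInputError("normalization maximum must be positive")


@dataclass
class GFDProfile:
    """Zone thresholds calibrated from a participant's GFD distribution."""

    q25: float
    median: float

    def __post_init__(self) -> None:
        if not (self.q25 <= self.median):
            raise InvalidInputError("q25 must not exceed the median")
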