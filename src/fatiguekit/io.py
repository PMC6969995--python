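"""Readers and writers for the delimited text formats the pipeline uses.

Signals arrive as TSV/CSV with a first column of time (s) or sample index
and one column per channel; the sampling rate comes from a JSON sidecar
(``<file>.json`` with ``{"fs": ...}``) or an explicit argument.  RR lists
are plain text, one interval per line, in seconds or milliseconds.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .types import ActivationSegment, SampledSignal, Tachogram

__all__ = [
    "read_signal",
    "write_signal",
    "read_rr",
    "write_activations",
    "write_peaks",
    "write_tachogram",
    "read_tachogram",
]


def _sidecar_fs(path: Path) -> float | None:
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return float(meta["fs"])
    return None


def read_signal(path: str | Path, fs: float | None = None,
                kind: str = "EMG", channel: int | str = 0) -> SampledSignal:
    """Read one channel of a delimited signal file.

    The first column is time (s) or a sample index and is used to infer
    the sampling rate when neither ``fs`` nor a JSON sidecar provides it.
    ``channel`` selects among the remaining columns by position or name.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    frame = pd.read_csv(path, sep=sep)
    if frame.shape[1] < 2:
        raise InvalidInputError(f"{path}: need a time column plus channels")
    t = frame.iloc[:, 0].to_numpy(dtype=float)
    if isinstance(channel, str):
        values = frame[channel].to_numpy(dtype=float)
        label = channel
    else:
        values = frame.iloc[:, channel + 1].to_numpy(dtype=float)
        label = str(frame.columns[channel + 1])
    if fs is None:
        fs = _sidecar_fs(path)
    if fs is None:
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise InvalidInputError(f"{path}: cannot infer sampling rate")
        # a time column in seconds has dt < 1; an index column has dt == 1
        # and no way to know the rate
        if dt >= 1.0:
            raise InvalidInputError(
                f"{path}: first column looks like a sample index; "
                "pass fs or provide a JSON sidecar")
        fs = 1.0 / dt
    return SampledSignal(values, float(fs), kind=kind, channel_label=label)


def write_signal(path: str | Path, signal: SampledSignal) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    frame = pd.DataFrame({"time_s": signal.times,
                          signal.channel_label or "ch0": signal.values})
    frame.to_csv(path, sep=sep, index=False)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps({"fs": signal.fs, "kind": signal.kind}))


def read_rr(path: str | Path, unit: str = "s", t0: float = 0.0) -> Tachogram:
    """Plain-text RR list (one interval per line) -> tachogram.

    ``unit`` in {"s", "ms"}; milliseconds are converted to seconds.
    """
    rr = np.loadtxt(Path(path), ndmin=1, dtype=float)
    if unit == "ms":
        rr = rr / 1000.0
    elif unit != "s":
        raise InvalidInputError(f"unknown RR unit {unit!r}")
    return Tachogram.from_rr(rr, t0=t0)


def write_activations(path: str | Path, segments: Sequence[ActivationSegment]) -> None:
    pd.DataFrame({
        "start_s": [s.start / s.fs for s in segments],
        "end_s": [s.end / s.fs for s in segments],
    }).to_csv(path, index=False)


def write_peaks(path: str | Path, peaks: np.ndarray, fs: float) -> None:
    pd.DataFrame({"time_s": np.asarray(peaks) / fs}).to_csv(path, index=False)


def write_tachogram(path: str | Path, tach: Tachogram) -> None:
    pd.DataFrame({"beat_time_s": tach.beat_times[1:],
                  "rr_s": tach.rr}).to_csv(path, index=False)


def read_tachogram(path: str | Path) -> Tachogram:
    frame = pd.read_csv(path)
    rr = frame["rr_s"].to_numpy(dtype=float)
    t_end = frame["beat_time_s"].to_numpy(dtype=float)
    beats = np.concatenate([[t_end[0] - rr[0]], t_end])
    return Tachogram(beat_times=beats, rr=rr)
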