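"""Synthetic EMG / ECG / RR generators with exact ground truth.

The generators emulate the statistical structure a fatiguing
constant-work-rate cycling trial imposes on the signals:

* EMG: repeated ~1 s activation bursts of band-pass-filtered white noise
  whose pass-band center (hence spectral median frequency) drifts
  linearly over the trial;
* RR tachogram: a linear mean-RR trend plus LF (0.1 Hz) and HF (0.25 Hz)
  sinusoidal modulation and white noise, realized as a point process;
* ECG: template QRS pulses placed at the cumulative RR beat times with
  baseline wander and additive noise.

An exercise phase ("acquisition +") uses the programmed drift signs; the
recovery phase ("acquisition -") mirrors them.  Every generator returns
its own ground truth so downstream tests never re-estimate it from data.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .types import ECG, EMG, SampledSignal, Tachogram

__all__ = [
    "SyntheticTrialSpec",
    "EMGGroundTruth",
    "synth_emg",
    "synth_rr",
    "synth_ecg",
    "synth_cohort",
    "CohortMember",
]

ACQ_PLUS = "acquisition_plus"
ACQ_MINUS = "acquisition_minus"


@dataclass
class SyntheticTrialSpec:
    """Parameters of one synthetic trial.

    Defaults describe a realistic exhausting cycling bout: ~10 min trial,
    one ~1 s burst every 2 s (pedaling at a steady cadence with one
    dominant-leg thrust per revolution), EMG median frequency starting
    near 90 Hz and losing ~18 Hz over the trial, mean RR shrinking from
    0.8 s as heart rate climbs, with LF/HF modulation depths of tens of
    milliseconds.
    """

    seed: int = 0
    fs: float = 1000.0
    duration_s: float = 600.0
    # EMG
    activation_rate: float = 0.5          # bursts per second
    activation_duration_s: float = 1.0
    mf_start: float = 90.0                # Hz
    mf_slope: float = -0.03               # Hz per second
    burst_bandwidth: float = 60.0         # Hz, pass-band width
    burst_amplitude: float = 1.0
    emg_noise_sd: float = 0.01
    # RR / ECG
    rr_start: float = 0.8                 # s
    rr_slope: float = -2.0e-4             # s per s
    lf_amp: float = 0.03                  # s, 0.1 Hz modulation depth
    hf_amp: float = 0.02                  # s, 0.25 Hz modulation depth
    lf_phase: float = 0.0                 # rad; autonomic oscillations are
    hf_phase: float = 0.0                 # not phase-locked across subjects
    rr_noise_sd: float = 0.01             # s
    ecg_noise_sd: float = 0.05
    phase: str = ACQ_PLUS

    def effective(self) -> "SyntheticTrialSpec":
        """Drift signs mirrored for the recovery phase.

        The returned spec is tagged as exercise-phase so the operation is
        idempotent (mirroring applies exactly once however many stages
        call it).
        """
        if self.phase == ACQ_MINUS:
            return replace(self, mf_slope=-self.mf_slope,
                           rr_slope=-self.rr_slope, phase=ACQ_PLUS)
        return self


@dataclass
class EMGGroundTruth:
    onsets_s: np.ndarray          # programmed burst onsets
    offsets_s: np.ndarray
    median_frequencies: np.ndarray  # programmed per-burst pass-band center
    mf_slope: float                 # Hz/s, against burst center times
    center_times_s: np.ndarray


def synth_emg(spec: SyntheticTrialSpec) -> tuple[SampledSignal, EMGGroundTruth]:
    """Synthetic EMG record with programmed activation bursts.

    Each burst is white noise through a 4th-order Butterworth band-pass of
    ``burst_bandwidth`` centered at ``mf_start + mf_slope * t_center``
    (the symmetric band makes that center the burst's expected spectral
    median frequency), tapered by a Tukey envelope; the baseline between
    bursts is low-level white noise.
    """
    spec = spec.effective()
    rng = np.random.default_rng(spec.seed)
    fs, n = spec.fs, int(spec.duration_s * spec.fs)
    x = rng.normal(0.0, spec.emg_noise_sd, size=n)

    period = 1.0 / spec.activation_rate
    burst_len = int(spec.activation_duration_s * fs)
    onsets, offsets, centers_f, centers_t = [], [], [], []
    t_on = period / 2.0
    env = sps.windows.tukey(burst_len, alpha=0.25)
    while t_on + spec.activation_duration_s < spec.duration_s:
        i0 = int(t_on * fs)
        t_c = t_on + spec.activation_duration_s / 2.0
        f_c = spec.mf_start + spec.mf_slope * t_c
        half = spec.burst_bandwidth / 2.0
        lo, hi = max(1.0, f_c - half), min(fs / 2 - 1.0, f_c + half)
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        burst = sps.sosfiltfilt(sos, rng.normal(0.0, 1.0, size=burst_len))
        sd = burst.std()
        if sd > 0:
            burst = burst / sd * spec.burst_amplitude
        x[i0:i0 + burst_len] += burst * env
        onsets.append(t_on)
        offsets.append(t_on + spec.activation_duration_s)
        centers_f.append(f_c)
        centers_t.append(t_c)
        t_on += period

    truth = EMGGroundTruth(
        onsets_s=np.asarray(onsets), offsets_s=np.asarray(offsets),
        median_frequencies=np.asarray(centers_f), mf_slope=spec.mf_slope,
        center_times_s=np.asarray(centers_t))
    sig = SampledSignal(x, fs, kind=EMG, channel_label="synthetic")
    return sig, truth


def rr_model(spec: SyntheticTrialSpec):
    """Instantaneous deterministic RR duration (s) at time t (vectorized)."""
    spec = spec.effective()

    def f(t):
        return (spec.rr_start + spec.rr_slope * np.asarray(t)
                + spec.lf_amp * np.sin(2 * np.pi * 0.1 * np.asarray(t)
                                       + spec.lf_phase)
                + spec.hf_amp * np.sin(2 * np.pi * 0.25 * np.asarray(t)
                                       + spec.hf_phase))
    return f


def synth_rr(spec: SyntheticTrialSpec) -> tuple[Tachogram, dict]:
    """Point-process tachogram with a linear trend and LF/HF modulation.

    Beats are placed by integrating the instantaneous RR duration
    (t_{k+1} = t_k + RR(t_k)); white noise of ``rr_noise_sd`` is added to
    each realized interval.  Returns the tachogram and the programmed
    truth (trend slope/intercept and modulation depths).
    """
    spec = spec.effective()
    rng = np.random.default_rng(spec.seed + 1)
    f = rr_model(spec)
    beats = [0.0]
    while beats[-1] < spec.duration_s:
        rr = float(f(beats[-1])) + rng.normal(0.0, spec.rr_noise_sd)
        rr = max(0.3, rr)
        beats.append(beats[-1] + rr)
    tach = Tachogram(beat_times=np.asarray(beats))
    truth = {"rr_slope": spec.rr_slope, "rr_start": spec.rr_start,
             "lf_amp": spec.lf_amp, "hf_amp": spec.hf_amp,
             "lf_freq": 0.1, "hf_freq": 0.25,
             "noise_sd": spec.rr_noise_sd}
    return tach, truth


def _qrs_template(fs: float) -> np.ndarray:
    """A stylized PQRST complex, 0.25 s long, unit R amplitude."""
    t = np.arange(int(0.25 * fs)) / fs - 0.125
    p = 0.12 * np.exp(-((t + 0.08) / 0.02) ** 2)
    q = -0.15 * np.exp(-((t + 0.02) / 0.008) ** 2)
    r = 1.0 * np.exp(-(t / 0.008) ** 2)
    s = -0.2 * np.exp(-((t - 0.02) / 0.008) ** 2)
    tw = 0.25 * np.exp(-((t - 0.09) / 0.03) ** 2)
    return p + q + r + s + tw


def synth_ecg(spec: SyntheticTrialSpec) -> tuple[SampledSignal, np.ndarray]:
    """ECG built from QRS templates at the beat times of :func:`synth_rr`.

    Returns the signal and the true R-peak times in seconds.
    """
    spec = spec.effective()
    rng = np.random.default_rng(spec.seed + 2)
    tach, _ = synth_rr(spec)
    fs = spec.fs
    n = int(np.ceil((tach.beat_times[-1] + 0.5) * fs))
    x = np.zeros(n)
    tpl = _qrs_template(fs)
    half = tpl.argmax()
    peak_times = []
    for bt in tach.beat_times:
        i = int(round(bt * fs)) + half
        lo = i - half
        hi = lo + tpl.size
        if lo < 0 or hi > n:
            continue
        x[lo:hi] += tpl
        peak_times.append(i / fs)
    t = np.arange(n) / fs
    x += 0.1 * np.sin(2 * np.pi * 0.3 * t)          # baseline wander
    x += rng.normal(0.0, spec.ecg_noise_sd, size=n)
    sig = SampledSignal(x, fs, kind=ECG, channel_label="synthetic")
    return sig, np.asarray(peak_times)


@dataclass
class CohortMember:
    participant_id: str
    plus: SyntheticTrialSpec
    minus: SyntheticTrialSpec


def synth_cohort(n_subjects: int, base_spec: SyntheticTrialSpec,
                 inter_subject_sd: float = 0.1,
                 seed: int = 0) -> list[CohortMember]:
    """Per-subject trial specs drawn around ``base_spec``.

    Starting values and drift slopes receive independent multiplicative
    jitter of relative SD ``inter_subject_sd``; each member holds an
    exercise ("acquisition +") and a mirrored recovery ("acquisition -")
    spec.  Identical seeds give bit-identical cohorts.
    """
    rng = np.random.default_rng(seed)
    members = []
    for i in range(n_subjects):
        jit = rng.normal(1.0, inter_subject_sd, size=4)
        jit = np.clip(jit, 0.5, 1.5)
        plus = replace(
            base_spec,
            seed=int(rng.integers(0, 2**31 - 1)),
            mf_start=base_spec.mf_start * jit[0],
            mf_slope=base_spec.mf_slope * jit[1],
            rr_start=base_spec.rr_start * jit[2],
            rr_slope=base_spec.rr_slope * jit[3],
            lf_phase=float(rng.uniform(0, 2 * np.pi)),
            hf_phase=float(rng.uniform(0, 2 * np.pi)),
            phase=ACQ_PLUS,
        )
        minus = replace(plus, seed=int(rng.integers(0, 2**31 - 1)),
                        phase=ACQ_MINUS)
        members.append(CohortMember(f"S{i+1:02d}", plus, minus))
    return members
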