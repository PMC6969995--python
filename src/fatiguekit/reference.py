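"""Reference trend statistics from the original 14-subject cycloergometry
study the method was developed on.

For each of the 14 individual fatigue descriptors (4 EMG, 10 HRV) the
table records the window-size / time-step combination that minimized the
coefficient of variation, the CV itself, the combined slope with the
half-length of its 95% confidence interval, and the direction of the
fatigue trend.  EMG rows pool 14 participants, HRV rows 11 (three heart
rate recordings were lost), so the CI uses 12 and 9 degrees of freedom
respectively.

These numbers serve two purposes: default CV weights for the Global
Fatigue Descriptor when no cohort recalibration is available, and an
internal consistency check (the printed half-length must equal
``t_{0.975, n-2} * CV * |m_comb|``).
"""
from __future__ import annotations

from dataclasses import dataclass

N_SUBJECTS_EMG = 14
N_SUBJECTS_HRV = 11


@dataclass(frozen=True)
class ReferenceTrend:
    param_id: str
    modality: str           # EMG | HRV
    ws: float               # activations (EMG) or seconds (HRV)
    ts: float               # same units as ws (the effective step)
    cv: float
    m_comb: float           # descriptor units per second
    ci_half_length: float
    direction: str          # increasing | decreasing

    @property
    def n_subjects(self) -> int:
        return N_SUBJECTS_EMG if self.modality == "EMG" else N_SUBJECTS_HRV


REFERENCE_TRENDS: tuple[ReferenceTrend, ...] = (
    ReferenceTrend("emg_median_frequency",         "EMG", 10, 1,  1.22e-2, -3.01e-2, 8.02e-4, "decreasing"),
    ReferenceTrend("emg_wavelet_median_frequency", "EMG", 10, 1,  2.42e-2, -2.87e-2, 1.52e-3, "decreasing"),
    ReferenceTrend("emg_major_frequency",          "EMG", 10, 1,  1.70e-2, -3.39e-2, 1.26e-3, "decreasing"),
    ReferenceTrend("emg_major_time",               "EMG", 25, 0,  3.94e-2, -5.19e-4, 4.46e-5, "decreasing"),
    ReferenceTrend("hrv_max_rr",                   "HRV", 30, 3,  1.25e-2, -1.82e-1, 5.16e-3, "decreasing"),
    ReferenceTrend("hrv_min_rr",                   "HRV", 30, 3,  8.94e-3, -1.71e-1, 3.46e-3, "decreasing"),
    ReferenceTrend("hrv_mean_rr",                  "HRV", 30, 3,  9.13e-3, -1.76e-1, 3.64e-3, "decreasing"),
    ReferenceTrend("hrv_rmssd",                    "HRV", 50, 45, 1.92e-2, -3.87e-3, 1.68e-4, "decreasing"),
    ReferenceTrend("hrv_sdnn",                     "HRV", 30, 3,  5.17e-2, -6.09e-3, 7.12e-4, "decreasing"),
    ReferenceTrend("hrv_triangular_index",         "HRV", 60, 30, 2.04e-2, -4.01e-2, 1.85e-3, "decreasing"),
    ReferenceTrend("hrv_sd2",                      "HRV", 30, 3,  4.25e-2, -1.09e-2, 1.05e-3, "decreasing"),
    ReferenceTrend("hrv_power_lf",                 "HRV", 30, 3,  5.78e-2, -1.51,    1.97e-1, "decreasing"),
    ReferenceTrend("hrv_power_hf",                 "HRV", 30, 3,  5.41e-2, -8.51e-1, 1.04e-1, "decreasing"),
    ReferenceTrend("hrv_median_frequency",         "HRV", 30, 3,  1.51e-2,  3.65e-3, 1.25e-4, "increasing"),
)


def reference_trend(param_id: str) -> ReferenceTrend:
    for row in REFERENCE_TRENDS:
        if row.param_id == param_id:
            return row
    raise KeyError(param_id)
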