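"""Fixed-effect meta-analysis of descriptor trends.

Per participant, an OLS line is fitted to each descriptor evolution
series, yielding a slope m_i and its sampling variance.  Slopes are pooled
across the cohort with inverse-variance weights w_i = 1/var(m_i):

    m_comb = sum(m_i w_i) / sum(w_i),    var_comb = 1 / sum(w_i)

The 95% CI uses the t quantile with n - 2 degrees of freedom, n being the
number of participants.  The coefficient of variation
CV = sd_comb / |m_comb| ranks window configurations (smaller = a
better-defined trend), and the two-stage acceptability test promotes a
descriptor to an individual fatigue descriptor (IFD) when its exercise
trend is significant and its recovery trend reverses or is uncertain.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidInputError, UndefinedResultError
from .types import CombinedTrend, ParameterSeries, RegressionResult, TrendDecision, WindowConfig

__all__ = [
    "fit_slope",
    "combine_slopes",
    "confidence_interval",
    "coefficient_of_variation",
    "combined_trend",
    "select_best_config",
    "trend_criteria",
    "forest_export",
]


def fit_slope(series: ParameterSeries) -> RegressionResult:
    """OLS slope of value vs. time with the classical slope variance
    ``residual variance / sum((t - mean t)^2)``."""
    t, y = series.times, series.values
    if t.size < 3:
        raise InvalidInputError("regression needs at least 3 points")
    if np.unique(t).size < 2:
        raise InvalidInputError("degenerate abscissa")
    res = stats.linregress(t, y)
    return RegressionResult(slope=float(res.slope),
                            var_slope=float(res.stderr ** 2),
                            n_points=int(t.size),
                            intercept=float(res.intercept))


def combine_slopes(results: Sequence[RegressionResult]) -> CombinedTrend:
    """Inverse-variance weighted pooling of per-participant slopes."""
    if len(results) == 0:
        raise InvalidInputError("no regression results to combine")
    m = np.array([r.slope for r in results])
    v = np.array([r.var_slope for r in results])
    if np.any(v <= 0):
        raise InvalidInputError("all slope variances must be positive")
    w = 1.0 / v
    m_comb = float(np.sum(m * w) / np.sum(w))
    var_comb = float(1.0 / np.sum(w))
    return CombinedTrend(m_comb=m_comb, var_comb=var_comb,
                         n_subjects=len(results))


def confidence_interval(trend: CombinedTrend, alpha: float = 0.05) -> tuple[float, float]:
    """``m_comb +/- t_{1-alpha/2, n-2} * sd_comb`` with n = participants."""
    n = trend.n_subjects
    if n < 3:
        raise InvalidInputError("CI needs at least 3 participants")
    tq = float(stats.t.ppf(1 - alpha / 2, n - 2))
    half = tq * trend.sd_comb
    return (trend.m_comb - half, trend.m_comb + half)


def ci_half_length(cv: float, m_comb: float, n_subjects: int,
                   alpha: float = 0.05) -> float:
    """CI half-length reconstructed from a printed (CV, combined slope)
    pair: ``t_{1-alpha/2, n-2} * CV * |m_comb|``."""
    tq = float(stats.t.ppf(1 - alpha / 2, n_subjects - 2))
    return tq * cv * abs(m_comb)


def coefficient_of_variation(trend: CombinedTrend) -> float:
    """``sd_comb / |m_comb|`` (absolute value: a CV is reported positive
    regardless of trend direction)."""
    if trend.m_comb == 0:
        raise UndefinedResultError("CV undefined for a zero combined slope")
    return float(trend.sd_comb / abs(trend.m_comb))


def combined_trend(results: Sequence[RegressionResult],
                   alpha: float = 0.05) -> CombinedTrend:
    """Pool slopes and fill in CI and CV in one call."""
    trend = combine_slopes(results)
    trend.ci = confidence_interval(trend, alpha=alpha)
    try:
        trend.cv = coefficient_of_variation(trend)
    except UndefinedResultError:
        trend.cv = None
    return trend


def select_best_config(
    trends: Mapping[WindowConfig, CombinedTrend],
) -> tuple[WindowConfig, CombinedTrend]:
    """Configuration minimizing the CV; ties favor the smaller window
    size, then the smaller time step."""
    valid = {c: t for c, t in trends.items() if t.cv is not None}
    if not valid:
        raise UndefinedResultError("no configuration yields a defined CV")
    best = min(valid, key=lambda c: (valid[c].cv, c.ws, c.ts_percent))
    return best, valid[best]


def trend_criteria(trend_plus: CombinedTrend,
                   trend_minus: CombinedTrend) -> TrendDecision:
    """Two-stage fatigue-trend acceptability test.

    (1) the exercise-phase CI must exclude zero; (2) the recovery-phase
    combined slope must reverse sign, or its CI must include zero (state
    of uncertainty).  A descriptor is an IFD iff both hold.
    """
    lo_p, hi_p = trend_plus.ci if trend_plus.ci else confidence_interval(trend_plus)
    lo_m, hi_m = trend_minus.ci if trend_minus.ci else confidence_interval(trend_minus)
    has_trend = not (lo_p <= 0.0 <= hi_p)
    reversal = np.sign(trend_minus.m_comb) != np.sign(trend_plus.m_comb)
    uncertain = lo_m <= 0.0 <= hi_m
    direction = "increasing" if trend_plus.m_comb > 0 else "decreasing"
    return TrendDecision(has_trend_plus=has_trend,
                         reversal_or_uncertain_minus=bool(reversal or uncertain),
                         direction=direction)


def forest_export(param_id: str,
                  results: Sequence[RegressionResult],
                  trend: CombinedTrend,
                  participant_ids: Sequence[str] | None = None,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Forest-plot data: one row per participant plus the combined row.

    Per-participant CIs use the t quantile with ``n_points - 2`` degrees
    of freedom; the ``weight`` column is normalized to sum to 1.
    """
    if participant_ids is None:
        participant_ids = [f"P{i+1:02d}" for i in range(len(results))]
    w = np.array([1.0 / r.var_slope for r in results])
    w_norm = w / w.sum()
    rows = []
    for pid, r, wn in zip(participant_ids, results, w_norm):
        tq = float(stats.t.ppf(1 - alpha / 2, max(1, r.n_points - 2)))
        half = tq * np.sqrt(r.var_slope)
        rows.append({"param": param_id, "participant": pid, "slope": r.slope,
                     "ci_lo": r.slope - half, "ci_hi": r.slope + half,
                     "weight": float(wn)})
    ci = trend.ci if trend.ci else confidence_interval(trend, alpha=alpha)
    rows.append({"param": param_id, "participant": "combined",
                 "slope": trend.m_comb, "ci_lo": ci[0], "ci_hi": ci[1],
                 "weight": 1.0})
    return pd.DataFrame(rows)
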