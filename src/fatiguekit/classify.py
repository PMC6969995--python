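"""Binary fatigue classifier: linear SVM on descriptor-trend features.

From every individual-fatigue-descriptor time series two features are
extracted per temporal segment:

    feature1 = mean of the max-normalized series
    feature2 = (P_end / P_start - 1) / (t_end - t_start)

With N = 4 EMG and M = 10 HRV descriptors that is a 2 (N + M) = 28-entry
vector per training example.  One "nonfatigued" and one "fatigued" example
per participant come from the early and late segment of each trial
(halves, or first/fourth quarters for sharper class prototypes).  Features
are z-scored, ranked by recursive feature elimination with leave-one-out
validation, and fed to a soft-margin linear SVM whose margin is
Platt-calibrated into a degree of certainty.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import InvalidInputError, UndefinedResultError
from .types import ParameterSeries

__all__ = [
    "NONFATIGUED",
    "FATIGUED",
    "TrainingExample",
    "ClassifierModel",
    "EvaluationReport",
    "feature1",
    "feature2",
    "segment_features",
    "calibration_maxima",
    "build_training_set",
    "examples_to_arrays",
    "select_features",
    "train_svm",
    "evaluate",
    "classify_stream",
    "pca_check",
]

NONFATIGUED = "nonfatigued"
FATIGUED = "fatigued"
_LABELS = {NONFATIGUED: 0, FATIGUED: 1}


@dataclass
class TrainingExample:
    features: np.ndarray
    label: str
    participant_id: str

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if not np.all(np.isfinite(self.features)):
            raise InvalidInputError("training features must be finite")
        if self.label not in _LABELS:
            raise InvalidInputError(f"unknown label {self.label!r}")


@dataclass
class ClassifierModel:
    """Linear decision rule sign(w.x + b) in standardized feature space,
    plus the scaler, selected feature indices and Platt calibration."""

    w: np.ndarray
    b: float
    selected_features: list[int]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    platt_a: float
    platt_b: float
    feature_names: list[str] = field(default_factory=list)

    def margins(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, self.selected_features]
        Z = (X - self.scaler_mean) / self.scaler_scale
        return Z @ self.w + self.b

    def probability_fatigued(self, X: np.ndarray) -> np.ndarray:
        m = self.margins(X)
        return 1.0 / (1.0 + np.exp(-(self.platt_a * m + self.platt_b)))

    def predict(self, X: np.ndarray) -> list[str]:
        return [FATIGUED if m > 0 else NONFATIGUED for m in self.margins(X)]

    def certainty(self, X: np.ndarray) -> np.ndarray:
        """Calibrated probability of the assigned class, in [0.5, 1]."""
        p = self.probability_fatigued(X)
        return np.maximum(p, 1.0 - p)


@dataclass
class EvaluationReport:
    fold_scores: np.ndarray
    mean_accuracy: float
    ci95: tuple[float, float]


def feature1(values: Sequence[float], max_value: float) -> float:
    """Mean of the max-normalized series; in [0, 1] when values <= max."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InvalidInputError("empty series")
    if max_value <= 0:
        raise InvalidInputError("max_value must be positive")
    return float(np.mean(v / max_value))


def feature2(p_start: float, p_end: float, t_start: float, t_end: float) -> float:
    """Relative variation rate ``(p_end/p_start - 1) / (t_end - t_start)``."""
    if p_start == 0:
        raise UndefinedResultError("relative variation undefined for p_start = 0")
    if t_end <= t_start:
        raise InvalidInputError("t_end must exceed t_start")
    return float((p_end / p_start - 1.0) / (t_end - t_start))


def segment_features(series: ParameterSeries, max_value: float,
                     t_lo: float, t_hi: float) -> tuple[float, float]:
    """(feature1, feature2) of the sub-series with t in [t_lo, t_hi)."""
    sel = (series.times >= t_lo) & (series.times < t_hi)
    if sel.sum() < 2:
        raise InvalidInputError("segment holds fewer than 2 series samples")
    t = series.times[sel]
    v = series.values[sel]
    return (feature1(v, max_value),
            feature2(v[0], v[-1], t[0], t[-1]))


def _segment_bounds(t0: float, t1: float, segmentation: str) -> tuple[tuple[float, float], tuple[float, float]]:
    span = t1 - t0
    if segmentation == "halves":
        return (t0, t0 + 0.5 * span), (t0 + 0.5 * span, t1 + 1e-9)
    if segmentation == "quarters":
        return (t0, t0 + 0.25 * span), (t0 + 0.75 * span, t1 + 1e-9)
    raise InvalidInputError(f"unknown segmentation {segmentation!r}")


def _max_for(maxima, pid: str, param: str) -> float:
    value = maxima[pid][param] if pid in maxima else maxima[param]
    return float(value)


def calibration_maxima(
    cohort_series: Mapping[str, Mapping[str, ParameterSeries]],
) -> dict[str, dict[str, float]]:
    """Per-participant normalization maxima from a calibration pass:
    each participant's own maximum of each descriptor series."""
    return {pid: {p: float(np.nanmax(s.values)) for p, s in per.items()
                  if len(s) and np.nanmax(s.values) > 0}
            for pid, per in cohort_series.items()}


def build_training_set(
    cohort_series: Mapping[str, Mapping[str, ParameterSeries]],
    maxima: Mapping,
    param_order: Sequence[str],
    segmentation: str = "halves",
) -> list[TrainingExample]:
    """Two examples per participant: early segment -> nonfatigued, late
    segment -> fatigued.

    ``cohort_series`` maps participant -> descriptor -> series;
    ``param_order`` fixes the feature layout (feature1, feature2 per
    descriptor, descriptors in order: 2 * len(param_order) entries).
    ``maxima`` holds the calibration maxima for normalization, either
    shared (param -> max) or per participant (participant -> param ->
    max); per-participant calibration is what removes between-subject
    baseline differences.
    """
    out: list[TrainingExample] = []
    for pid, per_param in cohort_series.items():
        missing = [p for p in param_order if p not in per_param]
        if missing:
            raise InvalidInputError(f"{pid}: missing series for {missing}")
        t0 = max(float(per_param[p].times[0]) for p in param_order)
        t1 = min(float(per_param[p].times[-1]) for p in param_order)
        early, late = _segment_bounds(t0, t1, segmentation)
        for bounds, label in ((early, NONFATIGUED), (late, FATIGUED)):
            feats: list[float] = []
            for p in param_order:
                f1, f2 = segment_features(per_param[p],
                                          _max_for(maxima, pid, p), *bounds)
                feats.extend([f1, f2])
            out.append(TrainingExample(np.asarray(feats), label, pid))
    return out


def examples_to_arrays(examples: Sequence[TrainingExample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([e.features for e in examples])
    y = np.array([_LABELS[e.label] for e in examples])
    return X, y


def _fit_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> tuple[StandardScaler, SVC]:
    scaler = StandardScaler().fit(X)
    svc = SVC(kernel="linear", C=C).fit(scaler.transform(X), y)
    return scaler, svc


def _loo_accuracy(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> float:
    correct = 0
    for train, test in LeaveOneOut().split(X):
        scaler, svc = _fit_linear_svm(X[train], y[train], C=C)
        correct += int(svc.predict(scaler.transform(X[test]))[0] == y[test][0])
    return correct / len(y)


def select_features(examples: Sequence[TrainingExample], C: float = 1.0) -> list[int]:
    """Recursive feature elimination ranked by |w|, validated leave-one-out.

    One feature is removed per iteration (the one with the smallest
    absolute standardized SVM weight); the subset with the highest LOO
    accuracy wins, ties resolved toward the smaller subset.
    """
    if len(examples) < 4:
        raise InvalidInputError("need at least 4 examples for selection")
    X, y = examples_to_arrays(examples)
    active = list(range(X.shape[1]))
    best_subset, best_score = list(active), -1.0
    while active:
        score = _loo_accuracy(X[:, active], y, C=C)
        if score >= best_score:  # >= prefers the later (smaller) subset
            best_score, best_subset = score, list(active)
        if len(active) == 1:
            break
        scaler, svc = _fit_linear_svm(X[:, active], y, C=C)
        weakest = int(np.argmin(np.abs(svc.coef_[0])))
        active.pop(weakest)
    return best_subset


def train_svm(examples: Sequence[TrainingExample],
              selected_features: Sequence[int] | None = None,
              C: float = 1.0,
              feature_names: Sequence[str] | None = None) -> ClassifierModel:
    """Fit the soft-margin linear SVM and Platt-calibrate its margin."""
    X, y = examples_to_arrays(examples)
    if selected_features is None:
        selected_features = list(range(X.shape[1]))
    sel = list(selected_features)
    scaler, svc = _fit_linear_svm(X[:, sel], y, C=C)
    w = svc.coef_[0].copy()
    b = float(svc.intercept_[0])
    margins = (scaler.transform(X[:, sel]) @ w + b).reshape(-1, 1)
    lr = LogisticRegression(C=1e3).fit(margins, y)
    return ClassifierModel(
        w=w, b=b, selected_features=sel,
        scaler_mean=scaler.mean_.copy(), scaler_scale=scaler.scale_.copy(),
        platt_a=float(lr.coef_[0][0]), platt_b=float(lr.intercept_[0]),
        feature_names=list(feature_names) if feature_names else [])


def _folds(examples: Sequence[TrainingExample], y: np.ndarray, k: int,
           seed: int | None):
    """Fold indices: when k equals the number of participants, each fold
    holds one participant's example pair (keeping the nonfatigued/fatigued
    pair structure intact and preventing within-subject leakage);
    otherwise plain stratified k-fold."""
    pids = [e.participant_id for e in examples]
    unique = list(dict.fromkeys(pids))
    if k == len(unique):
        if seed is not None:
            np.random.default_rng(seed).shuffle(unique)
        idx = np.arange(len(examples))
        for pid in unique:
            test = idx[[p == pid for p in pids]]
            train = idx[[p != pid for p in pids]]
            yield train, test
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=seed is not None,
                              random_state=seed)
        yield from skf.split(np.zeros(len(examples)), y)


def evaluate(examples: Sequence[TrainingExample], k: int = 11,
             C: float = 1.0, seed: int | None = None,
             selected_features: Sequence[int] | None = None) -> EvaluationReport:
    """Stratified k-fold accuracy with a t-based 95% CI across folds."""
    X, y = examples_to_arrays(examples)
    if selected_features is not None:
        X = X[:, list(selected_features)]
    scores = []
    for train, test in _folds(examples, y, k, seed):
        scaler, svc = _fit_linear_svm(X[train], y[train], C=C)
        pred = svc.predict(scaler.transform(X[test]))
        scores.append(float(np.mean(pred == y[test])))
    scores = np.asarray(scores)
    mean = float(scores.mean())
    if len(scores) > 1 and scores.std(ddof=1) > 0:
        half = float(stats.t.ppf(0.975, len(scores) - 1)
                     * scores.std(ddof=1) / np.sqrt(len(scores)))
    else:
        half = 0.0
    return EvaluationReport(fold_scores=scores, mean_accuracy=mean,
                            ci95=(mean - half, mean + half))


def classify_stream(
    model: ClassifierModel,
    series: Mapping[str, ParameterSeries],
    maxima: Mapping[str, float],
    param_order: Sequence[str],
    window_s: float = 60.0,
) -> pd.DataFrame:
    """Classify a trial over time from instantaneous descriptor values.

    At each shared-clock tick the feature1 analog is the instantaneous
    max-normalized value and the feature2 analog the relative variation
    across the trailing ``window_s`` seconds.  Returns a DataFrame with
    columns (t, label, certainty, p_nonfatigued).
    """
    from .gfd import align_series

    clock, aligned = align_series({p: series[p] for p in param_order})
    rows = []
    for i, t in enumerate(clock):
        j = int(np.searchsorted(clock, t - window_s, side="left"))
        feats: list[float] = []
        for p in param_order:
            v_now = aligned[p][i]
            v_then = aligned[p][j]
            feats.append(v_now / maxima[p])
            dt = clock[i] - clock[j]
            feats.append((v_now / v_then - 1.0) / dt if dt > 0 and v_then != 0 else 0.0)
        x = np.asarray(feats)[None, :]
        p_fat = float(model.probability_fatigued(x)[0])
        label = FATIGUED if p_fat > 0.5 else NONFATIGUED
        rows.append({"t": float(t), "label": label,
                     "certainty": max(p_fat, 1 - p_fat),
                     "p_nonfatigued": 1 - p_fat})
    return pd.DataFrame(rows)


def pca_check(examples: Sequence[TrainingExample],
              selected_features: Sequence[int] | None = None) -> np.ndarray:
    """Cumulative explained-variance ratios of the standardized features."""
    X, _ = examples_to_arrays(examples)
    if selected_features is not None:
        X = X[:, list(selected_features)]
    Z = StandardScaler().fit_transform(X)
    p = PCA().fit(Z)
    return np.cumsum(p.explained_variance_ratio_)
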