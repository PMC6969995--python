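"""Fatigue classifier: features, RFE, SVM training, evaluation, streaming."""
import numpy as np
import pytest

import fatiguekit as fk
from fatiguekit import classify as clf
from fatiguekit.exceptions import InvalidInputError, UndefinedResultError
from fatiguekit.types import ParameterSeries


def make_examples(rng, n_per_class=11, n_features=28, sep=3.0, flip=None):
    """Two Gaussian clouds separated by ``sep`` along a random direction."""
    direction = rng.normal(size=n_features)
    direction /= np.linalg.norm(direction)
    out = []
    for i in range(n_per_class):
        for label, sign in ((clf.NONFATIGUED, -1), (clf.FATIGUED, 1)):
            x = rng.normal(size=n_features) + sign * sep / 2 * direction
            out.append(clf.TrainingExample(x, label, f"S{i:02d}"))
    if flip is not None:
        labels = [e.label for e in out]
        flip.shuffle(labels)
        out = [clf.TrainingExample(e.features, l, e.participant_id)
               for e, l in zip(out, labels)]
    return out


class TestFeatures:
    def test_feature1_examples(self):
        assert clf.feature1([6.0, 6.0, 6.0], 6.0) == pytest.approx(1.0)
        assert clf.feature1([0.0, 0.0], 5.0) == 0.0
        assert clf.feature1([2.0, 4.0, 6.0], 6.0) == pytest.approx(2 / 3)

    def test_feature1_bounded(self, rng):
        v = rng.uniform(0, 5.0, 50)
        assert 0.0 <= clf.feature1(v, 5.0) <= 1.0

    def test_feature2_examples(self):
        assert clf.feature2(3.0, 3.0, 0.0, 10.0) == 0.0
        assert clf.feature2(1.0, 2.0, 0.0, 10.0) == pytest.approx(0.1)
        assert clf.feature2(2.0, 1.0, 0.0, 5.0) == pytest.approx(-0.1)

    def test_feature2_undefined_at_zero_start(self):
        with pytest.raises(UndefinedResultError):
            clf.feature2(0.0, 1.0, 0.0, 1.0)


def _cohort_series(n_subjects, params, rng, drop=0.5):
    """Linearly declining descriptor series per subject and parameter."""
    cohort = {}
    for i in range(n_subjects):
        per = {}
        for j, p in enumerate(params):
            t = np.arange(0.0, 300.0, 5.0)
            start = 1.0 + 0.1 * j
            v = start * (1 - drop * t / t[-1]) + rng.normal(0, 0.01, t.size)
            per[p] = ParameterSeries(p, f"S{i:02d}", None, t, v)
        cohort[f"S{i:02d}"] = per
    return cohort


class TestBuildTrainingSet:
    def test_two_examples_per_participant_28_features(self, rng):
        params = [f"p{k}" for k in range(14)]
        cohort = _cohort_series(11, params, rng)
        maxima = {p: 2.5 for p in params}
        examples = clf.build_training_set(cohort, maxima, params)
        assert len(examples) == 22
        assert all(e.features.size == 28 for e in examples)
        labels = [e.label for e in examples]
        assert labels.count(clf.NONFATIGUED) == 11

    def test_quarters_exclude_middle_half(self, rng):
        params = ["p0"]
        cohort = _cohort_series(1, params, rng)
        s = cohort["S00"]["p0"]
        t0, t1 = s.times[0], s.times[-1]
        early, late = clf._segment_bounds(t0, t1, "quarters")
        assert early[1] - t0 == pytest.approx(0.25 * (t1 - t0))
        assert t1 - late[0] == pytest.approx(0.25 * (t1 - t0), rel=1e-6)

    def test_halves_vs_quarters_feature1_gap(self, rng):
        """Quarter segments taken from the extremes of a declining series
        yield more distinct class prototypes than halves."""
        params = [f"p{k}" for k in range(3)]
        cohort = _cohort_series(6, params, rng)
        maxima = {p: 2.5 for p in params}
        halves = clf.build_training_set(cohort, maxima, params, "halves")
        quarters = clf.build_training_set(cohort, maxima, params, "quarters")

        def class_gap(examples):
            X, y = clf.examples_to_arrays(examples)
            f1 = X[:, ::2]  # feature1 columns
            return np.abs(f1[y == 0].mean() - f1[y == 1].mean())

        assert class_gap(quarters) >= class_gap(halves)


class TestSelectFeatures:
    def test_informative_feature_survives(self, rng):
        n = 20
        labels = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 6)) * 0.3
        X[:, 2] += labels * 4.0  # the one separating feature
        examples = [clf.TrainingExample(x, clf.FATIGUED if l else clf.NONFATIGUED,
                                        f"S{i}") for i, (x, l) in enumerate(zip(X, labels))]
        selected = clf.select_features(examples)
        assert 2 in selected

    def test_constant_feature_eliminated_before_informative(self, rng):
        n = 16
        labels = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 4)) * 0.1
        X[:, 0] = 5.0          # constant, zero weight after scaling
        X[:, 3] += labels * 3.0
        examples = [clf.TrainingExample(x, clf.FATIGUED if l else clf.NONFATIGUED,
                                        f"S{i}") for i, (x, l) in enumerate(zip(X, labels))]
        selected = clf.select_features(examples)
        assert 3 in selected
        assert selected == sorted(selected)
        assert all(0 <= i < 4 for i in selected)


class TestTrainSvm:
    def test_separable_clouds_perfect_training_accuracy(self, rng):
        examples = make_examples(rng, sep=4.0)
        model = clf.train_svm(examples)
        X, y = clf.examples_to_arrays(examples)
        pred = np.array([1 if p == clf.FATIGUED else 0
                         for p in model.predict(X)])
        assert np.mean(pred == y) == 1.0

    def test_symmetric_classes_have_small_bias(self, rng):
        X0 = rng.normal(size=(30, 4)) + 2.0
        examples = ([clf.TrainingExample(x, clf.NONFATIGUED, "a") for x in X0]
                    + [clf.TrainingExample(-x, clf.FATIGUED, "b") for x in X0])
        model = clf.train_svm(examples)
        assert abs(model.b) < 0.2

    def test_decision_invariant_to_margin_rescaling(self, rng):
        examples = make_examples(rng, sep=3.0)
        model = clf.train_svm(examples)
        X, _ = clf.examples_to_arrays(examples)
        before = model.predict(X)
        model.w = model.w * 7.3
        model.b = model.b * 7.3
        assert model.predict(X) == before

    def test_margin_sign_matches_hand_solved_toy_problem(self):
        # two points per class on a line: the maximal-margin separator of
        # {(0,), (1,)} vs {(3,), (4,)} crosses at x = 2
        examples = [clf.TrainingExample([0.0], clf.NONFATIGUED, "a"),
                    clf.TrainingExample([1.0], clf.NONFATIGUED, "b"),
                    clf.TrainingExample([3.0], clf.FATIGUED, "c"),
                    clf.TrainingExample([4.0], clf.FATIGUED, "d")]
        model = clf.train_svm(examples)
        assert model.predict(np.array([[1.9]])) == [clf.NONFATIGUED]
        assert model.predict(np.array([[2.1]])) == [clf.FATIGUED]


class TestEvaluate:
    def test_separable_cohort_perfect_accuracy(self, rng):
        examples = make_examples(rng, sep=5.0)
        report = clf.evaluate(examples, k=11, seed=3)
        assert report.mean_accuracy == 1.0

    def test_permuted_labels_fall_to_chance(self, rng):
        examples = make_examples(rng, sep=5.0,
                                 flip=np.random.default_rng(99))
        report = clf.evaluate(examples, k=11, seed=3)
        assert 0.2 <= report.mean_accuracy <= 0.8

    def test_k_equal_n_is_leave_one_out(self, rng):
        examples = make_examples(rng, n_per_class=6, sep=5.0)
        report = clf.evaluate(examples, k=len(examples) // 2, seed=1)
        assert report.fold_scores.size == len(examples) // 2


class TestStreamAndPca:
    def test_stream_certainty_declines_on_drifting_trial(self, rng):
        params = [f"p{k}" for k in range(4)]
        cohort = _cohort_series(8, params, rng)
        maxima = {p: 2.5 for p in params}
        examples = clf.build_training_set(cohort, maxima, params)
        model = clf.train_svm(examples)
        stream = clf.classify_stream(model, cohort["S00"], maxima, params,
                                     window_s=60.0)
        slope = np.polyfit(stream["t"], stream["p_nonfatigued"], 1)[0]
        assert slope <= 0
        assert ((stream["certainty"] >= 0.5) & (stream["certainty"] <= 1.0)).all()

    def test_pca_two_informative_directions_dominate(self, rng):
        n = 40
        latent = rng.normal(size=(n, 2))
        mixing = rng.normal(size=(2, 9))
        X = latent @ mixing + 0.05 * rng.normal(size=(n, 9))
        examples = [clf.TrainingExample(x, clf.NONFATIGUED if i % 2 else clf.FATIGUED,
                                        f"S{i}") for i, x in enumerate(X)]
        cum = clf.pca_check(examples)
        assert cum[-1] == pytest.approx(1.0)
        assert cum[1] >= 0.6

    def test_pca_isotropic_features_share_variance(self, rng):
        X = rng.normal(size=(300, 5))
        examples = [clf.TrainingExample(x, clf.NONFATIGUED, "a") for x in X]
        cum = clf.pca_check(examples)
        ratios = np.diff(np.concatenate([[0.0], cum]))
        assert np.all(ratios < 0.35)
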