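import numpy as np
import pytest
from scipy import stats

from drowsnet.nn import ConvBiLSTM
from drowsnet.preprocess import FIVE_CLASS, TWO_CLASS, EpochSet, make_folds
from drowsnet.train_eval import (
    EvalReport,
    NetworkClassifier,
    TrainConfig,
    accuracy_from_confusion,
    chance_level,
    confusion_matrix,
    cross_validate,
    loso_validate,
    metrics_from_confusion,
    paired_ttest,
    train,
)
from test_model import tiny_spec


def toy_epochset(n_per_class=24, n_ch=6, n_samp=12, seed=0, effect=4.0, kss=(2, 9)):
    """Two-class toy data: class 1 carries a strong 10 Hz component."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_samp) / 100.0
    xs, ks = [], []
    for cls, k in enumerate(kss):
        x = rng.standard_normal((n_per_class, n_ch, n_samp))
        if cls == 1:
            x += effect * np.sin(2 * np.pi * 10 * t)[None, None, :]
        xs.append(x)
        ks.extend([k] * n_per_class)
    epochs = np.concatenate(xs)
    n = epochs.shape[0]
    return EpochSet(epochs=epochs, kss=np.array(ks), trial_index=np.arange(n) % 4,
                    fs=100.0, channel_labels=[f"ch{i}" for i in range(n_ch)])


class TestTrain:
    def test_loss_decreases_on_separable_data(self):
        es = toy_epochset()
        model = ConvBiLSTM(tiny_spec(2), seed=0)
        model, trace = train(model, es.epochs, es.labels2, TrainConfig(epochs=8, batch_size=16, seed=0))
        assert len(trace) == 8
        assert trace[-1] < trace[0]
        acc = np.mean(model.predict(es.epochs) == es.labels2)
        assert acc > 0.8

    def test_same_seed_identical_trace(self):
        es = toy_epochset()
        cfg = TrainConfig(epochs=3, batch_size=16, seed=4)
        _, t1 = train(ConvBiLSTM(tiny_spec(2), seed=1), es.epochs, es.labels2, cfg)
        _, t2 = train(ConvBiLSTM(tiny_spec(2), seed=1), es.epochs, es.labels2, cfg)
        assert t1 == t2

    def test_single_epoch_checkpoint(self):
        es = toy_epochset()
        cfg = TrainConfig(epochs=1, batch_size=16, seed=0)
        m1, trace = train(ConvBiLSTM(tiny_spec(2), seed=2), es.epochs, es.labels2, cfg)
        assert len(trace) == 1
        m2, _ = train(ConvBiLSTM(tiny_spec(2), seed=2), es.epochs, es.labels2, cfg)
        for a, b in zip(m1.get_state(), m2.get_state()):
            assert np.array_equal(a, b)

    def test_checkpoint_is_argmin_of_trace(self):
        es = toy_epochset(n_per_class=16)
        model = ConvBiLSTM(tiny_spec(2), seed=0)
        model, trace = train(model, es.epochs, es.labels2,
                             TrainConfig(epochs=5, batch_size=16, seed=0))
        # retrain stopping exactly at the argmin epoch: states must agree
        best = int(np.argmin(trace)) + 1
        model2, trace2 = train(ConvBiLSTM(tiny_spec(2), seed=0), es.epochs, es.labels2,
                               TrainConfig(epochs=best, batch_size=16, seed=0))
        assert trace2 == trace[:best]
        for a, b in zip(model.get_state(), model2.get_state()):
            assert np.allclose(a, b)

    def test_single_class_raises(self):
        es = toy_epochset(kss=(2, 2))
        with pytest.raises(ValueError):
            train(ConvBiLSTM(tiny_spec(2), seed=0), es.epochs, es.labels2, TrainConfig(epochs=1))


class TestConfusion:
    def test_perfect_predictions_identity(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        assert np.allclose(confusion_matrix(y, y, 3), np.eye(3))

    def test_constructed_ratio(self):
        targets = np.zeros(100, dtype=int)
        preds = np.concatenate([np.zeros(86, dtype=int), np.ones(14, dtype=int)])
        targets = np.concatenate([targets, np.ones(50, dtype=int)])
        preds = np.concatenate([preds, np.ones(50, dtype=int)])
        cm = confusion_matrix(preds, targets, 2)
        assert cm[0, 0] == pytest.approx(0.86)
        assert cm[1, 0] == pytest.approx(0.14)
        assert cm[1, 1] == pytest.approx(1.0)

    def test_columns_sum_to_one(self, rng):
        preds = rng.integers(0, 4, 1000)
        targets = rng.integers(0, 4, 1000)
        cm = confusion_matrix(preds, targets, 4)
        assert np.allclose(cm.sum(axis=0), 1.0, atol=1e-9)

    def test_random_predictions_uniform(self, rng):
        n = 100_000
        preds = rng.integers(0, 5, n)
        targets = rng.integers(0, 5, n)
        cm = confusion_matrix(preds, targets, 5)
        assert np.allclose(cm, 0.2, atol=0.01)

    def test_empty_target_class_raises(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 0], [0, 0], 2)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0], 2)


class TestMetrics:
    def test_published_style_values(self):
        cm = np.array([[0.86, 0.12], [0.14, 0.88]])
        acc, sens, spec = metrics_from_confusion(cm, [100, 100])
        assert sens == pytest.approx(0.86)
        assert spec == pytest.approx(0.88)
        assert acc == pytest.approx(0.87)

    def test_identity_confusion(self):
        acc, sens, spec = metrics_from_confusion(np.eye(2), [10, 30])
        assert acc == sens == spec == 1.0

    def test_balanced_accuracy_counting_oracle(self, rng):
        preds = np.concatenate([rng.integers(0, 2, 400), rng.integers(0, 2, 400)])
        targets = np.concatenate([np.zeros(400, dtype=int), np.ones(400, dtype=int)])
        cm = confusion_matrix(preds, targets, 2)
        acc, r1, r2 = metrics_from_confusion(cm, [400, 400])
        assert acc == pytest.approx((r1 + r2) / 2)
        assert acc == pytest.approx(np.mean(preds == targets))

    def test_multiclass_sens_spec_raises(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.eye(5), [1] * 5)

    def test_chance_level(self):
        assert chance_level(5) == pytest.approx(0.2)
        assert chance_level(2) == pytest.approx(0.5)


class _ConstantClassifier:
    def __init__(self, value=0):
        self.value = value

    def fit(self, x, y):
        return self

    def predict(self, x):
        return np.full(x.shape[0], self.value)


class _NearestMeanClassifier:
    """Cheap deterministic stand-in for fold mechanics tests."""

    def fit(self, x, y):
        self.classes_ = np.unique(y)
        self.means_ = np.stack([x[y == c].mean(axis=0).ravel() for c in self.classes_])
        return self

    def predict(self, x):
        flat = x.reshape(x.shape[0], -1)
        d = ((flat[:, None, :] - self.means_[None]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d, axis=1)]


class TestCrossValidate:
    def test_constant_model_accuracy_is_prevalence(self):
        es = toy_epochset(n_per_class=24)
        folds = make_folds(es, k=4, seed=0)
        report = cross_validate(lambda: _ConstantClassifier(0), es, folds, TWO_CLASS)
        # drowsy column is all-wrong, so overall accuracy = alert prevalence
        assert report.mean_accuracy == pytest.approx(0.5, abs=1e-9)
        assert report.sensitivity == pytest.approx(1.0)
        assert report.specificity == pytest.approx(0.0)

    def test_std_is_sample_std(self):
        report = EvalReport(fold_accuracies=[0.6, 0.7, 0.8, 0.9],
                            confusion=np.eye(2), n_test=[10] * 4)
        assert report.std_accuracy == pytest.approx(np.std([0.6, 0.7, 0.8, 0.9], ddof=1))

    def test_separable_beats_chance(self):
        es = toy_epochset(n_per_class=40)
        folds = make_folds(es, k=4, seed=0)
        report = cross_validate(lambda: _NearestMeanClassifier(), es, folds, TWO_CLASS)
        assert report.mean_accuracy > 0.9

    def test_network_classifier_interface(self):
        es = toy_epochset(n_per_class=16)
        folds = make_folds(es, k=2, seed=0)
        factory = lambda: NetworkClassifier(tiny_spec(2), TrainConfig(epochs=2, batch_size=16))  # noqa: E731
        report = cross_validate(factory, es, folds, TWO_CLASS)
        assert len(report.fold_accuracies) == 2
        assert np.allclose(report.confusion.sum(axis=0), 1.0)


def _subject_epochset(seed, effect=4.0):
    return toy_epochset(n_per_class=20, seed=seed, effect=effect)


class TestLoso:
    def test_folds_are_subject_disjoint(self):
        sets = [_subject_epochset(s) for s in range(3)]
        report = loso_validate(lambda: _NearestMeanClassifier(), sets, TWO_CLASS)
        assert len(report.fold_accuracies) == 3
        assert report.n_test == [len(s) for s in sets]

    def test_single_subject_raises(self):
        with pytest.raises(ValueError):
            loso_validate(lambda: _NearestMeanClassifier(), [_subject_epochset(0)], TWO_CLASS)

    def test_identically_distributed_subjects_match_cv(self):
        sets = [_subject_epochset(s) for s in range(3)]
        loso = loso_validate(lambda: _NearestMeanClassifier(), sets, TWO_CLASS)
        pooled = EpochSet.concat(sets)
        folds = make_folds(pooled, k=3, seed=0)
        cv = cross_validate(lambda: _NearestMeanClassifier(), pooled, folds, TWO_CLASS)
        assert abs(loso.mean_accuracy - cv.mean_accuracy) < 0.15

    def test_shifted_subject_scores_lower(self):
        sets = [_subject_epochset(s) for s in range(2)]
        odd = _subject_epochset(99, effect=0.0)  # no class signal for this subject
        report = loso_validate(lambda: _NearestMeanClassifier(), sets + [odd], TWO_CLASS)
        assert report.fold_accuracies[2] < min(report.fold_accuracies[:2])


class TestPairedTtest:
    def test_hand_computed_value(self):
        # differences (1, 1, 1, 2): mean 1.25, sd 0.5, se 0.25 -> t = 5
        t, p = paired_ttest([2, 3, 4, 7], [1, 2, 3, 5])
        assert t == pytest.approx(5.0)
        t_ref, p_ref = stats.ttest_rel([2, 3, 4, 7], [1, 2, 3, 5])
        assert t == pytest.approx(t_ref)
        assert p == pytest.approx(p_ref)

    def test_antisymmetry(self):
        a, b = [0.8, 0.7, 0.9, 0.6], [0.5, 0.6, 0.7, 0.55]
        t1, p1 = paired_ttest(a, b)
        t2, p2 = paired_ttest(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_raises_or_returns_one(self):
        with pytest.raises(ValueError):
            paired_ttest([1, 2, 3], [1, 2, 3])
        t, p = paired_ttest([1, 2, 3], [1, 2, 3], zero_variance="one")
        assert (t, p) == (0.0, 1.0)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [2.0])
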