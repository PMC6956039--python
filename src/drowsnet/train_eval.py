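"""Training protocol, cross-validation, and the metric suite.

Metrics follow the column-normalized confusion convention: column j is the
target class, row i the prediction, and entry (i, j) the fraction of class-j
samples predicted as class i.  For the 2-class task the positive class is
"alert" (class 0): sensitivity is alert recall, specificity drowsy recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import stats

from .nn.model import ConvBiLSTM, ModelSpec
from .nn.losses import softmax_cross_entropy
from .nn.optim import Adam
from .preprocess import EpochSet, FoldAssignment, LabelScheme, TWO_CLASS

__all__ = [
    "TrainConfig",
    "EvalReport",
    "train",
    "NetworkClassifier",
    "confusion_matrix",
    "metrics_from_confusion",
    "accuracy_from_confusion",
    "chance_level",
    "cross_validate",
    "loso_validate",
    "paired_ttest",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; the checkpoint rule keeps the weights from the
    training epoch with the lowest mean training loss."""

    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def train(model: ConvBiLSTM, x: np.ndarray, y: np.ndarray,
          cfg: TrainConfig = TrainConfig()) -> tuple[ConvBiLSTM, list[float]]:
    """Cross-entropy training with per-epoch shuffling and Adam updates.

    Returns the model restored to its lowest-training-loss checkpoint and the
    per-epoch loss trace (length ``cfg.epochs``).
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), lr=cfg.lr)
    n = x.shape[0]
    trace: list[float] = []
    best_loss = np.inf
    best_state = None
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            loss = model.loss_and_grad(x[idx], y[idx], training=True, rng=rng)
            opt.step()
            losses.append(loss)
        epoch_loss = float(np.mean(losses))
        trace.append(epoch_loss)
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_state = model.get_state()
    if best_state is not None:
        model.set_state(best_state)
    return model, trace


class Classifier(Protocol):
    def fit(self, x: np.ndarray, y: np.ndarray) -> "Classifier": ...
    def predict(self, x: np.ndarray) -> np.ndarray: ...


class NetworkClassifier:
    """fit/predict wrapper around the conv/bi-LSTM network."""

    def __init__(self, spec: ModelSpec, train_config: TrainConfig = TrainConfig()):
        self.spec = spec
        self.train_config = train_config
        self.model: ConvBiLSTM | None = None
        self.loss_trace: list[float] | None = None

    def fit(self, x: np.ndarray, y: np.ndarray) -> "NetworkClassifier":
        self.model = ConvBiLSTM(self.spec, seed=self.train_config.seed)
        self.model, self.loss_trace = train(self.model, x, y, self.train_config)
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("fit must be called before predict")
        return self.model.predict(x)


def confusion_matrix(predictions: Sequence[int], targets: Sequence[int], k: int) -> np.ndarray:
    """Column-normalized K x K confusion matrix.

    Entry (i, j) = count(pred == i and target == j) / count(target == j);
    every column sums to 1.  Raises if any target class is absent.
    """
    pred = np.asarray(predictions, dtype=int)
    targ = np.asarray(targets, dtype=int)
    if pred.shape != targ.shape:
        raise ValueError("predictions and targets must have equal length")
    if np.any((pred < 0) | (pred >= k)) or np.any((targ < 0) | (targ >= k)):
        raise ValueError(f"labels must lie in [0, {k})")
    counts = np.zeros((k, k))
    np.add.at(counts, (pred, targ), 1.0)
    col = counts.sum(axis=0)
    if np.any(col == 0):
        missing = np.flatnonzero(col == 0).tolist()
        raise ValueError(f"no target samples for class(es) {missing}; ratios undefined")
    return counts / col[None, :]


def accuracy_from_confusion(confusion: np.ndarray, counts: Sequence[int]) -> float:
    """Overall fraction correct, recombining recalls with class prevalences."""
    counts = np.asarray(counts, dtype=float)
    return float(np.diag(confusion) @ counts / counts.sum())


def metrics_from_confusion(confusion: np.ndarray, counts: Sequence[int]) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) for the 2-class task.

    Sensitivity = alert (class 0) recall; specificity = drowsy (class 1)
    recall.  Raises for K != 2.
    """
    confusion = np.asarray(confusion)
    if confusion.shape != (2, 2):
        raise ValueError("sensitivity/specificity are defined for K=2 only")
    accuracy = accuracy_from_confusion(confusion, counts)
    return accuracy, float(confusion[0, 0]), float(confusion[1, 1])


def chance_level(k: int) -> float:
    """Expected accuracy of a uniform-random classifier on K balanced classes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 1.0 / k


@dataclass
class EvalReport:
    """Per-fold metrics plus the pooled column-normalized confusion matrix."""

    fold_accuracies: list[float]
    confusion: np.ndarray
    n_test: list[int]
    sensitivity: float | None = None
    specificity: float | None = None
    fold_predictions: list[np.ndarray] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))


def _evaluate_folds(factory: Callable[[], Classifier], splits: list[tuple[np.ndarray, np.ndarray]],
                    x: np.ndarray, y: np.ndarray, k_classes: int) -> EvalReport:
    fold_acc: list[int | float] = []
    n_test: list[int] = []
    all_pred: list[np.ndarray] = []
    all_targ: list[np.ndarray] = []
    fold_predictions: list[np.ndarray] = []
    for train_idx, test_idx in splits:
        assert np.intersect1d(train_idx, test_idx).size == 0, "train/test leakage"
        clf = factory()
        clf.fit(x[train_idx], y[train_idx])
        pred = np.asarray(clf.predict(x[test_idx]))
        fold_acc.append(float(np.mean(pred == y[test_idx])))
        n_test.append(test_idx.size)
        all_pred.append(pred)
        all_targ.append(y[test_idx])
        fold_predictions.append(pred)
    confusion = confusion_matrix(np.concatenate(all_pred), np.concatenate(all_targ), k_classes)
    report = EvalReport(fold_accuracies=fold_acc, confusion=confusion, n_test=n_test,
                        fold_predictions=fold_predictions)
    if k_classes == 2:
        counts = np.bincount(np.concatenate(all_targ), minlength=2)
        _, report.sensitivity, report.specificity = metrics_from_confusion(confusion, counts)
    return report


def cross_validate(factory: Callable[[], Classifier], epochs: EpochSet,
                   folds: FoldAssignment, scheme: LabelScheme = TWO_CLASS) -> EvalReport:
    """k-fold cross-validation over a fold assignment; one model per fold."""
    if folds.k < 2:
        raise ValueError("at least 2 folds are required")
    y = epochs.labels(scheme)
    splits = [
        (np.flatnonzero(folds.train_mask(f)), np.flatnonzero(folds.test_mask(f)))
        for f in range(folds.k)
    ]
    return _evaluate_folds(factory, splits, epochs.epochs, y, scheme.n_classes)


def loso_validate(factory: Callable[[], Classifier], epoch_sets: Sequence[EpochSet],
                  scheme: LabelScheme = TWO_CLASS) -> EvalReport:
    """Leave-one-subject-out validation: one fold per held-out subject."""
    if len(epoch_sets) < 2:
        raise ValueError("at least 2 subjects are required for leave-one-subject-out")
    pooled = EpochSet.concat(list(epoch_sets))
    y = pooled.labels(scheme)
    subj = pooled.subject_index
    splits = [
        (np.flatnonzero(subj != s), np.flatnonzero(subj == s))
        for s in range(len(epoch_sets))
    ]
    return _evaluate_folds(factory, splits, pooled.epochs, y, scheme.n_classes)


def paired_ttest(scores_a: Sequence[float], scores_b: Sequence[float],
                 zero_variance: str = "error") -> tuple[float, float]:
    """Classic paired t-test on the per-fold score differences.

    t = mean(d) / (sd(d) / sqrt(n)) with df = n - 1, two-sided p.  With
    ``zero_variance='one'`` a degenerate difference vector returns p = 1
    instead of raising.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired score vectors must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("at least 2 paired observations are required")
    d = a - b
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        if zero_variance == "one":
            return 0.0, 1.0
        raise ValueError("zero variance of paired differences; t undefined")
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return t, p
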