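"""Cross-validated evaluation of the downsample-classify-vote pipeline.

The cross-validation granularity follows the experimental protocol: folds
are stratified over the *downsampled* signals, so the M children of one
recording usually land in several folds (and a recording's brothers may
sit on both sides of a split).  Because every item is in exactly one test
fold, one full CV round yields one predicted label per downsampled
signal; the M labels of each recording are then voted on and the
per-recording decision is scored against the true class.

Metrics: total accuracy Ac, per-class one-vs-rest sensitivity
Se = TP/(TP+FN) and specificity Sp = TN/(TN+FP), all in percent, and a
3x4 row-normalized confusion table whose fourth column is the
indeterminate outcome.  An indeterminate decision counts as a
misclassification for Ac and as a negative prediction for every class.
A ``group_by_parent`` mode confines all M children of a recording to a
single fold, measuring across-recording rather than within-recording
generalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifier import TrainingConfig, predict_labels, train_mlpnn
from .features import FeatureVector
from .simulate import CLASSES
from .vote import INDETERMINATE, bmmv

DECISION_COLUMNS = (*CLASSES, INDETERMINATE)


@dataclass
class FoldAssignment:
    k: int
    fold_of: np.ndarray  # fold index per item
    stratified: bool
    seed: int


@dataclass
class RunMetrics:
    """Scores of one repetition (one full k-fold CV round)."""

    accuracy: float
    sensitivity: dict[str, float]
    specificity: dict[str, float]
    confusion_pct: np.ndarray  # 3 true-class rows x 4 decision columns, rows sum to 100
    confusion_counts: np.ndarray
    downsample_accuracy: float = np.nan
    indeterminate_pct: float = np.nan


@dataclass
class EvaluationReport:
    runs: list[RunMetrics]
    k: int
    M: int
    seed: int

    def _collect(self, getter) -> np.ndarray:
        return np.asarray([getter(r) for r in self.runs], dtype=float)

    def mean_sd(self, getter) -> tuple[float, float]:
        vals = self._collect(getter)
        return float(np.mean(vals)), float(np.std(vals))

    def summary(self) -> dict:
        """Aggregate mean ± SD of every measure over the repetitions."""
        out: dict = {"k": self.k, "M": self.M, "runs": len(self.runs)}
        out["accuracy"] = self.mean_sd(lambda r: r.accuracy)
        out["downsample_accuracy"] = self.mean_sd(lambda r: r.downsample_accuracy)
        out["indeterminate_pct"] = self.mean_sd(lambda r: r.indeterminate_pct)
        out["sensitivity"] = {c: self.mean_sd(lambda r, c=c: r.sensitivity[c]) for c in CLASSES}
        out["specificity"] = {c: self.mean_sd(lambda r, c=c: r.specificity[c]) for c in CLASSES}
        conf = np.stack([r.confusion_pct for r in self.runs])
        out["confusion_pct_mean"] = conf.mean(axis=0)
        out["confusion_pct_sd"] = conf.std(axis=0)
        return out

    def to_dict(self) -> dict:
        s = self.summary()
        s["confusion_pct_mean"] = s["confusion_pct_mean"].tolist()
        s["confusion_pct_sd"] = s["confusion_pct_sd"].tolist()
        s["confusion_columns"] = list(DECISION_COLUMNS)
        s["confusion_rows"] = list(CLASSES)
        return s


def _derive_seed(*key: int) -> int:
    ss = np.random.SeedSequence([int(k) for k in key])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def stratified_kfold(labels: Sequence[str], k: int, seed: int = 0) -> FoldAssignment:
    """Deterministic stratified fold assignment over labeled items.

    Every fold keeps each class's share within one item of its share in
    the whole dataset; requires at least k items of every class and
    k >= 2 (with k = 1 no train/test split exists).
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2 (k = 1 leaves nothing to train on)")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        small = classes[np.argmin(counts)]
        raise ValueError(f"class {small!r} has {counts.min()} items, fewer than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(labels), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_of[test_idx] = f
    return FoldAssignment(k=k, fold_of=fold_of, stratified=True, seed=seed)


def compute_metrics(true_labels: Sequence[str], decisions: Sequence[str]) -> RunMetrics:
    """Ac, per-class Se/Sp and the row-normalized confusion table.

    ``decisions`` may contain the indeterminate outcome; true labels may
    not.  Rows of the confusion table are true classes, columns are the
    three class decisions plus indeterminate, normalized by the true-class
    totals so every row sums to 100%.
    """
    true_labels = np.asarray(true_labels)
    decisions = np.asarray(decisions)
    if len(true_labels) != len(decisions):
        raise ValueError("true labels and decisions must have equal length")
    bad = set(true_labels) - set(CLASSES)
    if bad:
        raise ValueError(f"true labels {sorted(bad)} outside the class set {CLASSES}")
    bad = set(decisions) - set(DECISION_COLUMNS)
    if bad:
        raise ValueError(f"decisions {sorted(bad)} outside {DECISION_COLUMNS}")

    counts = np.zeros((len(CLASSES), len(DECISION_COLUMNS)), dtype=int)
    row = {c: i for i, c in enumerate(CLASSES)}
    col = {c: j for j, c in enumerate(DECISION_COLUMNS)}
    for t, d in zip(true_labels, decisions):
        counts[row[t], col[d]] += 1

    total = len(true_labels)
    correct = int(np.trace(counts[:, : len(CLASSES)]))
    accuracy = 100.0 * correct / total

    sensitivity: dict[str, float] = {}
    specificity: dict[str, float] = {}
    for i, c in enumerate(CLASSES):
        tp = counts[i, i]
        fn = counts[i].sum() - tp  # wrong class or indeterminate
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            warnings.warn(f"no true items of class {c!r}; sensitivity undefined")
            sensitivity[c] = np.nan
        else:
            sensitivity[c] = 100.0 * tp / (tp + fn)
        specificity[c] = 100.0 * tn / (tn + fp) if tn + fp else np.nan

    row_totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        confusion_pct = 100.0 * counts / row_totals
    indeterminate_pct = 100.0 * counts[:, -1].sum() / total
    return RunMetrics(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        confusion_pct=confusion_pct,
        confusion_counts=counts,
        indeterminate_pct=indeterminate_pct,
    )


def _default_classifier_factory(X_tr, y_tr, config: TrainingConfig, fold_seed: int):
    from dataclasses import replace

    model = train_mlpnn(X_tr, replace(config, seed=fold_seed), labels=y_tr)
    return lambda X: predict_labels(model, X)


def cross_validate(
    features: Sequence[FeatureVector],
    k: int = 10,
    config: TrainingConfig = TrainingConfig(),
    M: int | None = None,
    runs: int = 1,
    seed: int = 0,
    group_by_parent: bool = False,
    classifier_factory: Callable | None = None,
) -> EvaluationReport:
    """Repeated stratified k-fold CV with per-recording majority voting.

    Each run draws fresh folds (seed derived from ``seed`` and the run
    index), trains one classifier per fold rotation, collects each
    recording's M predicted labels from whichever test folds they landed
    in, votes, and scores the per-recording decisions.
    ``classifier_factory(X_tr, y_tr, config, fold_seed) -> predict_fn``
    may replace the MLP (used for oracle/stub checks).
    """
    if classifier_factory is None:
        classifier_factory = _default_classifier_factory
    X = np.vstack([fv.fused for fv in features])
    y = np.asarray([fv.label for fv in features])
    parents = np.asarray([fv.parent_id for fv in features])
    offsets = np.asarray([fv.offset for fv in features])
    if any(p is None for p in parents) or any(o is None for o in offsets):
        raise ValueError("all feature vectors must carry parent_id and offset")
    parents = parents.astype(str)
    offsets = offsets.astype(int)

    unique_parents, parent_counts = np.unique(parents, return_counts=True)
    if M is None:
        M = int(parent_counts[0])
    if np.any(parent_counts != M):
        bad = unique_parents[parent_counts != M][0]
        raise ValueError(f"recording {bad!r} has {parent_counts[parent_counts != M][0]} "
                         f"downsampled signals, expected M={M}")
    parent_label = {}
    for p, lab in zip(parents, y):
        parent_label.setdefault(p, lab)

    run_metrics: list[RunMetrics] = []
    for r in range(runs):
        run_seed = _derive_seed(seed, r)
        if group_by_parent:
            p_labels = np.asarray([parent_label[p] for p in unique_parents])
            p_folds = stratified_kfold(p_labels, k, seed=run_seed)
            fold_lookup = dict(zip(unique_parents, p_folds.fold_of))
            fold_of = np.asarray([fold_lookup[p] for p in parents])
        else:
            fold_of = stratified_kfold(y, k, seed=run_seed).fold_of

        predicted = np.empty(len(y), dtype=y.dtype)
        for f in range(k):
            test = fold_of == f
            train = ~test
            if set(y[train]) != set(y):
                raise ValueError("a class is absent from a training fold; use fewer folds")
            predict_fn = classifier_factory(X[train], y[train], config, _derive_seed(run_seed, f))
            predicted[test] = predict_fn(X[test])

        decisions = []
        truths = []
        for p in unique_parents:
            mask = parents == p
            order = np.argsort(offsets[mask])
            decisions.append(bmmv(tuple(predicted[mask][order]), parent_id=str(p)).decision)
            truths.append(parent_label[p])
        metrics = compute_metrics(truths, decisions)
        metrics.downsample_accuracy = 100.0 * float(np.mean(predicted == y))
        run_metrics.append(metrics)
    return EvaluationReport(runs=run_metrics, k=k, M=M, seed=seed)
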