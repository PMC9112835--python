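"""Genotype classification of glutamate maps with an SVM.

Features are the standardized in-mask pixel intensities (standardization
parameters come from training rows only).  Splitting is stratified by
genotype at the subject level: augmented copies always follow their
source subject, and only original (non-augmented) test images are
scored.  The SVM optimizer is scikit-learn's; this module owns the
experiment protocol and the metric formulas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from glucest.harmonize import AugmentedSet

POSITIVE_LABEL = "AD"


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts; positive class = AD."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must count at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    degenerate: tuple[str, ...] = ()  # metrics hit a zero-denominator convention

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1,
                "degenerate": list(self.degenerate)}


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, precision, recall and F1 from the confusion matrix.

    Zero denominators follow the usual conventions (rate = 0) and are
    flagged in ``degenerate``.
    """
    degenerate: list[str] = []
    accuracy = (cm.tp + cm.tn) / cm.total
    if cm.tp + cm.fp == 0:
        precision, flag = 0.0, True
    else:
        precision, flag = cm.tp / (cm.tp + cm.fp), False
    if flag:
        degenerate.append("precision")
    if cm.tp + cm.fn == 0:
        recall = 0.0
        degenerate.append("recall")
    else:
        recall = cm.tp / (cm.tp + cm.fn)
    if precision + recall == 0:
        f1 = 0.0
        degenerate.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(accuracy=accuracy, precision=precision,
                         recall=recall, f1=f1, degenerate=tuple(degenerate))


def f1_from_rates(a: float, b: float) -> float:
    """Harmonic mean of two rates in percent: f = 2ab / (a + b)."""
    if a + b == 0:
        raise ValueError("rates sum to zero; harmonic mean undefined")
    if not (0 < a <= 100 and 0 < b <= 100):
        raise ValueError("rates must be in (0, 100]")
    return 2.0 * a * b / (a + b)


def split_subjects(subject_ids: Sequence[str], labels: Sequence[str],
                   test_fraction: float = 0.30, seed: int = 0,
                   ) -> tuple[list[str], list[str]]:
    """Stratified subject-level split; returns (train_ids, test_ids).

    Augmented copies are not split here — they inherit their source
    subject's side, which prevents augmentation leakage.
    """
    ids = list(dict.fromkeys(subject_ids))  # unique, order-preserving
    if len(ids) != len(subject_ids):
        raise ValueError("subject_ids must be unique (pass source subjects)")
    lab_by_id = dict(zip(subject_ids, labels))
    classes = set(lab_by_id.values())
    if len(classes) < 2:
        raise ValueError("need at least two classes to split")
    for c in classes:
        if sum(1 for v in lab_by_id.values() if v == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 subjects")
    if test_fraction == 0:
        return ids, []
    train, test = train_test_split(
        ids, test_size=test_fraction, random_state=seed,
        stratify=[lab_by_id[i] for i in ids])
    return list(train), list(test)


def _feature_rows(dataset: AugmentedSet, mask: np.ndarray) -> np.ndarray:
    return np.stack([img[mask] for img in dataset.images])


def confusion_from_predictions(y_true: Sequence[str],
                               y_pred: Sequence[str],
                               positive: str = POSITIVE_LABEL) -> ConfusionMatrix:
    yt = np.asarray(y_true) == positive
    yp = np.asarray(y_pred) == positive
    return ConfusionMatrix(
        tp=int(np.sum(yt & yp)), fp=int(np.sum(~yt & yp)),
        fn=int(np.sum(yt & ~yp)), tn=int(np.sum(~yt & ~yp)))


def train_and_eval_svm(train: AugmentedSet, test: AugmentedSet,
                       mask: np.ndarray, kernel: str = "rbf",
                       C: float = 1.0, seed: int = 0,
                       ) -> tuple[ConfusionMatrix, MetricsReport]:
    """Fit an SVM on the training set and score original test images.

    Standardization is fit on training rows only.  Augmented copies in
    the test set (identified by their provenance transform) are excluded
    from scoring.
    """
    if len(set(train.labels)) < 2:
        raise ValueError("training set must contain both classes")
    x_train = _feature_rows(train, mask)
    scaler = StandardScaler().fit(x_train)
    clf = SVC(kernel=kernel, C=C, random_state=seed)
    clf.fit(scaler.transform(x_train), train.labels)

    keep = [k for k, p in enumerate(test.provenance)
            if p["transform"]["kind"] == "identity"]
    if not keep:
        raise ValueError("test set has no original (non-augmented) images")
    x_test = np.stack([test.images[k][mask] for k in keep])
    y_true = [test.labels[k] for k in keep]
    y_pred = clf.predict(scaler.transform(x_test))
    cm = confusion_from_predictions(y_true, y_pred)
    return cm, metrics(cm)
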