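"""Jackknife / k-fold evaluation, confusion matrix, accuracy, and ROC.

Conventions: membrane is the positive class.  A false positive (a
nonmembrane sequence predicted membrane) is a Type I error and a false
negative a Type II error.  Overall accuracy is
``100 * (TP + TN) / (TP + TN + FP + FN)`` reported to two decimals; the
per-class ("output") accuracies are the column-wise rates TP/(TP+FN) and
TN/(TN+FP).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Literal

import numpy as np

#: trainer(X_train, y_train, seed) -> score function over a feature matrix.
Trainer = Callable[[np.ndarray, np.ndarray, int], Callable[[np.ndarray], np.ndarray]]

POSITIVE = "membrane"
NEGATIVE = "nonmembrane"


class EvaluationError(ValueError):
    """Invalid evaluation input."""


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class ROCResult:
    """Threshold-swept ROC points (monotone, (0,0) to (1,1)) and AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "ifub":
        y = np.where(y.astype(float) > 0.5, POSITIVE, NEGATIVE)
    vals = set(np.unique(y).tolist())
    if not vals <= {POSITIVE, NEGATIVE}:
        raise EvaluationError(f"labels must be binary membrane/nonmembrane, got {vals}")
    return y


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """2x2 contingency counts with membrane as the positive class."""
    yt = _as_binary(y_true)
    yp = _as_binary(y_pred)
    if yt.size != yp.size:
        raise EvaluationError("y_true and y_pred differ in length")
    tp = int(np.sum((yt == POSITIVE) & (yp == POSITIVE)))
    tn = int(np.sum((yt == NEGATIVE) & (yp == NEGATIVE)))
    fp = int(np.sum((yt == NEGATIVE) & (yp == POSITIVE)))
    fn = int(np.sum((yt == POSITIVE) & (yp == NEGATIVE)))
    return ConfusionMatrix(TP=tp, TN=tn, FP=fp, FN=fn)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy percentage, two decimals."""
    if cm.total == 0:
        raise EvaluationError("empty confusion matrix")
    return round(100.0 * (cm.TP + cm.TN) / cm.total, 2)


def class_accuracy(cm: ConfusionMatrix, which: Literal["positive", "negative"]) -> float:
    """Per-condition column accuracy: TP/(TP+FN) or TN/(TN+FP), as percent."""
    if which == "positive":
        denom = cm.TP + cm.FN
        num = cm.TP
    elif which == "negative":
        denom = cm.TN + cm.FP
        num = cm.TN
    else:
        raise ValueError(f"which must be 'positive' or 'negative', got {which!r}")
    if denom == 0:
        raise EvaluationError(f"no instances of the {which} class")
    return round(100.0 * num / denom, 2)


def jackknife(
    X: np.ndarray,
    y,
    trainer: Trainer,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, ConfusionMatrix]:
    """Leave-one-out evaluation: each instance predicted by a model trained
    on the other n-1 (the trainer re-fits any scaler inside each fold).

    Returns (scores, predicted labels, confusion matrix).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    yt = _as_binary(y)
    n = X.shape[0]
    if n < 2:
        raise EvaluationError("jackknife needs at least 2 instances")
    scores = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        score_fn = trainer(X[mask], yt[mask], seed)
        scores[i] = float(np.asarray(score_fn(X[i : i + 1])).ravel()[0])
    preds = np.where(scores >= threshold, POSITIVE, NEGATIVE)
    return scores, preds, confusion(yt, preds)


def stratified_folds(y, k: int, seed: int = 0, stratify: bool = True) -> np.ndarray:
    """Seeded assignment of instances to k mutually exclusive folds.

    With stratification the class proportions are balanced across folds;
    fold sizes differ by at most one.
    """
    yt = np.asarray(y)
    n = yt.size
    if k < 2:
        raise EvaluationError("k must be >= 2")
    if k > n:
        raise EvaluationError(f"k={k} exceeds dataset size n={n}")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if stratify:
        counter = 0
        for cls in np.unique(yt):
            idx = np.flatnonzero(yt == cls)
            rng.shuffle(idx)
            for j, i in enumerate(idx):
                assignment[i] = (counter + j) % k
            counter += idx.size
    else:
        idx = rng.permutation(n)
        for j, i in enumerate(idx):
            assignment[i] = j % k
    return assignment


def kfold(
    X: np.ndarray,
    y,
    k: int,
    trainer: Trainer,
    seed: int = 0,
    threshold: float = 0.5,
    stratify: bool = True,
) -> tuple[np.ndarray, np.ndarray, ConfusionMatrix]:
    """k-fold cross-validation; k == n reduces to the jackknife."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    yt = _as_binary(y)
    folds = stratified_folds(yt, k, seed, stratify)
    scores = np.empty(X.shape[0])
    for fold in range(k):
        test = folds == fold
        score_fn = trainer(X[~test], yt[~test], seed)
        scores[test] = np.asarray(score_fn(X[test])).ravel()
    preds = np.where(scores >= threshold, POSITIVE, NEGATIVE)
    return scores, preds, confusion(yt, preds)


def roc_curve(scores, labels) -> ROCResult:
    """ROC by threshold sweep over the unique scores; AUC by trapezoid rule."""
    s = np.asarray(scores, dtype=float)
    yt = _as_binary(labels)
    pos = yt == POSITIVE
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("ROC needs both classes present")
    order = np.argsort(-s, kind="stable")
    sorted_pos = pos[order].astype(float)
    tps = np.cumsum(sorted_pos)
    fps = np.cumsum(1.0 - sorted_pos)
    # collapse ties: keep the last index of each distinct score
    distinct = np.flatnonzero(np.diff(s[order])) if s.size > 1 else np.array([], dtype=int)
    keep = np.r_[distinct, s.size - 1]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc)


# --- reporting --------------------------------------------------------------


def write_confusion_tsv(path: str | Path, cm: ConfusionMatrix) -> None:
    """Confusion matrix plus overall and per-class accuracies as TSV."""
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"TP\t{cm.TP}\nFN\t{cm.FN}\nFP\t{cm.FP}\nTN\t{cm.TN}\n")
        fh.write(f"overall_accuracy_pct\t{accuracy(cm)}\n")
        if cm.TP + cm.FN:
            fh.write(f"membrane_accuracy_pct\t{class_accuracy(cm, 'positive')}\n")
        if cm.TN + cm.FP:
            fh.write(f"nonmembrane_accuracy_pct\t{class_accuracy(cm, 'negative')}\n")


def write_roc_csv(path: str | Path, roc: ROCResult) -> None:
    with open(path, "w") as fh:
        fh.write("fpr,tpr\n")
        for f, t in zip(roc.fpr, roc.tpr):
            fh.write(f"{f},{t}\n")
        fh.write(f"# AUC,{roc.auc}\n")


def plot_roc(path: str | Path, roc: ROCResult) -> None:
    """ROC curve figure (sensitivity vs false positive rate)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(roc.fpr, roc.tpr, label=f"AUC = {roc.auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate (sensitivity)")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_accuracy_bars(path: str | Path, cm: ConfusionMatrix) -> None:
    """Histogram of per-class and overall accuracy."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = ["membrane", "nonmembrane", "overall"]
    values = [class_accuracy(cm, "positive"), class_accuracy(cm, "negative"), accuracy(cm)]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.bar(labels, values, color=["#4878d0", "#ee854a", "#6acc64"])
    ax.set_ylabel("Accuracy (%)")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
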