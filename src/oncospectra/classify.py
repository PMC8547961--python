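"""Linear-SVM diagnostics under repeated stratified cross-validation.

Binary performance is summarized as the mean and standard deviation of the
per-fold test AUCs over 10-fold cross-validation repeated 10 times, plus a
pooled ROC built from the concatenated held-out decision scores. Operating
points follow the study conventions: the ROC vertex closest to the
upper-left corner, and the sensitivity at 95% specificity (conservative
step convention, no interpolation). Multiclass problems use one-vs-one
linear SVMs with majority vote (ties broken by aggregate decision score)
and are reported as a confusion matrix of per-class accuracies.

The ROC/AUC computation is authored here (threshold sweep + trapezoid); it
coincides exactly with the Mann-Whitney probability estimate, counting ties
as one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "CVEvaluation",
    "OperatingPoint",
    "ConfusionSummary",
    "train_linear_svm",
    "roc_and_auc",
    "optimal_point",
    "sensitivity_at_specificity",
    "cv_evaluate",
    "multiclass_cv",
]


@dataclass
class OperatingPoint:
    sensitivity: float
    specificity: float
    threshold: float


@dataclass
class CVEvaluation:
    fold_aucs: np.ndarray           # (n_repeats * n_folds,)
    auc_mean: float
    auc_sd: float
    pooled_roc: pd.DataFrame        # columns fpr, tpr, threshold
    pooled_auc: float
    n_folds: int
    n_repeats: int
    seed: int
    operating_point: OperatingPoint | None = None
    sens_at_95spec: float | None = None


@dataclass
class ConfusionSummary:
    counts: pd.DataFrame            # true class x predicted class
    per_class_accuracy: pd.Series
    overall_accuracy_mean: float
    overall_accuracy_sd: float
    fold_accuracies: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def normalized(self) -> pd.DataFrame:
        return self.counts.div(self.counts.sum(axis=1), axis=0)


def train_linear_svm(X, y, C: float = 1.0, tol: float = 1e-4) -> SVC:
    """Soft-margin linear SVM exposing continuous decision scores
    ("disease likelihood")."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if np.unique(y).size < 2:
        raise ValueError("at least two classes are required")
    clf = SVC(kernel="linear", C=C, tol=tol)
    clf.fit(X, y)
    return clf


# ------------------------------------------------------------------ ROC / AUC
def roc_and_auc(scores, labels):
    """ROC by threshold sweep over unique scores and trapezoidal AUC.

    ``labels`` must contain exactly two values; the larger one is the
    positive class. A prediction is positive when score >= threshold. The
    AUC equals the Mann-Whitney estimate with ties counted one half.
    Returns ``(roc DataFrame with fpr/tpr/threshold, auc)``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("exactly two label values are required")
    pos = labels == classes[-1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())

    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    p_sorted = pos[order]
    tp = np.cumsum(p_sorted)
    fp = np.cumsum(~p_sorted)
    # collapse tied scores onto one ROC vertex
    last_of_tie = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tp[last_of_tie] / n_pos]
    fpr = np.r_[0.0, fp[last_of_tie] / n_neg]
    thr = np.r_[np.inf, s_sorted[last_of_tie]]
    auc = float(np.trapezoid(tpr, fpr))
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return roc, auc


def optimal_point(roc: pd.DataFrame) -> OperatingPoint:
    """ROC vertex minimizing the distance to the upper-left corner (FPR 0,
    TPR 1); ties broken toward higher sensitivity."""
    if len(roc) == 0:
        raise ValueError("empty ROC")
    fpr = roc["fpr"].to_numpy()
    tpr = roc["tpr"].to_numpy()
    d = np.hypot(1.0 - tpr, fpr)
    best = np.flatnonzero(d <= d.min() + 1e-12)
    i = best[np.argmax(tpr[best])]
    return OperatingPoint(sensitivity=float(tpr[i]),
                          specificity=float(1.0 - fpr[i]),
                          threshold=float(roc["threshold"].iloc[i]))


def sensitivity_at_specificity(roc: pd.DataFrame, spec: float = 0.95) -> float:
    """Largest sensitivity among ROC vertices with specificity >= ``spec``
    (step convention, no interpolation)."""
    ok = (1.0 - roc["fpr"].to_numpy()) >= spec - 1e-12
    if not ok.any():
        raise ValueError(f"specificity {spec} is not attained by any vertex")
    return float(roc["tpr"].to_numpy()[ok].max())


# ------------------------------------------------------------------------- CV
def cv_evaluate(X, y, folds: int = 10, repeats: int = 10, seed: int = 0,
                C: float = 1.0) -> CVEvaluation:
    """Repeated stratified k-fold evaluation of a binary linear SVM.

    Folds are re-randomized each repeat from ``seed``; the model is fitted
    on training folds only (all per-sample preprocessing happens upstream,
    so no statistics leak across the split). Reports per-fold AUCs, their
    mean and SD, and a pooled ROC with its operating points.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("binary evaluation requires exactly two classes")
    if counts.min() < folds:
        raise ValueError("smallest class is smaller than the fold count")

    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                 random_state=seed)
    fold_aucs = []
    pooled_scores, pooled_labels = [], []
    for train, test in cv.split(X, y):
        clf = train_linear_svm(X[train], y[train], C=C)
        s = clf.decision_function(X[test])
        # orient scores toward the lexicographically larger (positive) class
        if not np.array_equal(clf.classes_, classes):
            s = -s
        _, auc = roc_and_auc(s, y[test])
        fold_aucs.append(auc)
        pooled_scores.append(s)
        pooled_labels.append(y[test])
    fold_aucs = np.asarray(fold_aucs)
    roc, pooled_auc = roc_and_auc(np.concatenate(pooled_scores),
                                  np.concatenate(pooled_labels))
    return CVEvaluation(
        fold_aucs=fold_aucs,
        auc_mean=float(fold_aucs.mean()),
        auc_sd=float(fold_aucs.std(ddof=1)),
        pooled_roc=roc,
        pooled_auc=pooled_auc,
        n_folds=folds,
        n_repeats=repeats,
        seed=seed,
        operating_point=optimal_point(roc),
        sens_at_95spec=sensitivity_at_specificity(roc, 0.95),
    )


def multiclass_cv(X, y, folds: int = 10, repeats: int = 10, seed: int = 0,
                  C: float = 1.0) -> ConfusionSummary:
    """One-vs-one linear SVM under repeated stratified k-fold CV.

    Confusion counts accumulate over all held-out folds; per-class accuracy
    is the class recall of the accumulated matrix; overall accuracy is
    reported as mean +- SD over folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("at least two classes are required")
    if counts.min() < folds:
        raise ValueError("smallest class is smaller than the fold count")

    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                 random_state=seed)
    cm = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    fold_acc = []
    for train, test in cv.split(X, y):
        clf = SVC(kernel="linear", C=C)  # natively one-vs-one with voting
        clf.fit(X[train], y[train])
        pred = clf.predict(X[test])
        for t, p in zip(y[test], pred):
            cm.loc[t, p] += 1
        fold_acc.append(float(np.mean(pred == y[test])))
    fold_acc = np.asarray(fold_acc)
    per_class = pd.Series(np.diag(cm) / cm.sum(axis=1).to_numpy(),
                          index=classes, name="per_class_accuracy")
    return ConfusionSummary(
        counts=cm,
        per_class_accuracy=per_class,
        overall_accuracy_mean=float(fold_acc.mean()),
        overall_accuracy_sd=float(fold_acc.std(ddof=1)),
        fold_accuracies=fold_acc,
    )
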