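"""Evaluation layer: confusion metrics, overlap scores, one-way ANOVA,
and a thin harness over standard classifier families.

Segmentation overlap is summarized by the Jaccard index
``J = TP/(TP+FP+FN)`` and the Dice coefficient ``D = 2TP/(2TP+FP+FN)``
(algebraically ``D = 2J/(1+J)``).  Classifier comparisons use the textbook
one-way ANOVA decomposition with the upper-tail F probability from
:mod:`scipy.stats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "AnovaTable",
    "ConfusionCounts",
    "EvaluationReport",
    "anova_from_sums",
    "anova_oneway",
    "confusion_metrics",
    "counts_from_masks",
    "f_critical",
    "train_eval_classifier",
]

CLASSIFIER_FAMILIES = (
    "quadratic-svm",
    "weighted-knn",
    "medium-nn",
    "trilayer-nn",
    "ensemble-subspace-discriminant",
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvaluationReport:
    """Scalar metrics in [0, 1]; undefined entries are NaN."""

    accuracy: float
    sensitivity: float
    specificity: float
    fnr: float
    fpr: float
    f1: float
    jaccard: float
    dice: float

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy_pct,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "fnr": self.fnr,
            "fpr": self.fpr,
            "f1": self.f1,
            "jaccard": self.jaccard,
            "dice": self.dice,
        }


@dataclass(frozen=True)
class AnovaTable:
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    f_stat: float
    p_value: float

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within


def confusion_metrics(c: ConfusionCounts) -> EvaluationReport:
    """All report metrics from raw counts; ratios with zero denominators
    come back as NaN rather than raising."""

    def _ratio(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    jac = _ratio(c.tp, c.tp + c.fp + c.fn)
    return EvaluationReport(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=sens,
        specificity=spec,
        fnr=1.0 - sens if not math.isnan(sens) else math.nan,
        fpr=1.0 - spec if not math.isnan(spec) else math.nan,
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        jaccard=jac,
        dice=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def counts_from_masks(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixel-overlap counts between two binary masks of equal shape."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int(np.count_nonzero(pred & truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
    )


def anova_from_sums(
    ss_between: float, df_between: int, ss_within: float, df_within: int
) -> AnovaTable:
    """ANOVA table from pre-computed sums of squares and degrees of freedom."""
    if df_between <= 0 or df_within <= 0:
        raise ValueError("degrees of freedom must be positive")
    if ss_between < 0 or ss_within < 0:
        raise ValueError("sums of squares must be non-negative")
    ms_b = ss_between / df_between
    ms_w = ss_within / df_within
    if ms_w == 0:
        f = math.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        f = ms_b / ms_w
        p = float(sps.f.sf(f, df_between, df_within))
    return AnovaTable(
        ss_between=ss_between,
        ss_within=ss_within,
        df_between=df_between,
        df_within=df_within,
        ms_between=ms_b,
        ms_within=ms_w,
        f_stat=f,
        p_value=p,
    )


def anova_oneway(groups: list[np.ndarray]) -> AnovaTable:
    """Textbook one-way decomposition of a list of numeric samples."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least two values")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_b = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return anova_from_sums(
        float(ss_b), len(groups) - 1, float(ss_w), all_vals.size - len(groups)
    )


def f_critical(df_between: int, df_within: int, alpha: float = 0.05) -> float:
    """Upper ``alpha`` critical value of the F distribution."""
    if df_between <= 0 or df_within <= 0:
        raise ValueError("degrees of freedom must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    return float(sps.f.ppf(1.0 - alpha, df_between, df_within))


def _micro_counts(y_true, y_pred) -> ConfusionCounts:
    from sklearn.metrics import confusion_matrix

    cm = confusion_matrix(y_true, y_pred)
    if cm.shape == (2, 2):
        tn, fp, fn, tp = (int(v) for v in cm.ravel())
        return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
    # micro-average: pool per-class one-vs-rest counts
    tp = int(np.trace(cm))
    total = int(cm.sum())
    fp = total - tp
    fn = fp
    tn = total * cm.shape[0] - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _macro_report(y_true, y_pred) -> EvaluationReport:
    classes = np.unique(np.concatenate([np.asarray(y_true), np.asarray(y_pred)]))
    reports = []
    for cls in classes:
        t = np.asarray(y_true) == cls
        p = np.asarray(y_pred) == cls
        reports.append(confusion_metrics(counts_from_masks(p, t)))
    return EvaluationReport(
        **{
            k: float(np.nanmean([getattr(r, k) for r in reports]))
            for k in (
                "accuracy", "sensitivity", "specificity", "fnr", "fpr",
                "f1", "jaccard", "dice",
            )
        }
    )


def make_classifier(family: str, seed: int = 42):
    """An off-the-shelf estimator for one of the supported families.

    Presets follow the common desktop-toolbox configurations: quadratic SVM
    (degree-2 polynomial kernel), weighted KNN (10 neighbours, inverse
    squared distance), medium NN (one hidden layer of 25), trilayer NN
    (three hidden layers of 10), and an ensemble of linear discriminants on
    random feature subspaces.  All inputs are standardized in-pipeline.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import BaggingClassifier
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    if family == "quadratic-svm":
        est = SVC(kernel="poly", degree=2, coef0=1.0, C=1.0, random_state=seed)
    elif family == "weighted-knn":
        est = KNeighborsClassifier(
            n_neighbors=10, weights=lambda d: 1.0 / (d**2 + 1e-12)
        )
    elif family == "medium-nn":
        est = MLPClassifier(
            hidden_layer_sizes=(25,), max_iter=1000, random_state=seed
        )
    elif family == "trilayer-nn":
        est = MLPClassifier(
            hidden_layer_sizes=(10, 10, 10), max_iter=1000, random_state=seed
        )
    elif family == "ensemble-subspace-discriminant":
        est = BaggingClassifier(
            estimator=LinearDiscriminantAnalysis(),
            n_estimators=30,
            max_features=0.5,
            bootstrap=False,
            random_state=seed,
        )
    else:
        raise ValueError(
            f"unknown family {family!r}; choose from {CLASSIFIER_FAMILIES}"
        )
    return make_pipeline(StandardScaler(), est)


def train_eval_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    family: str,
    test_size: float = 0.2,
    k_folds: int | None = None,
    averaging: str = "micro",
    seed: int = 42,
) -> EvaluationReport:
    """Fit a classifier family and report held-out metrics.

    By default a stratified 80:20 split is used; ``k_folds`` switches to
    stratified k-fold with metrics pooled over the out-of-fold predictions.
    Multi-class counts are micro-averaged (``averaging="macro"`` averages
    per-class metrics instead).
    """
    from sklearn.model_selection import (
        StratifiedKFold,
        cross_val_predict,
        train_test_split,
    )

    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least two classes")
    clf = make_classifier(family, seed=seed)
    if k_folds is not None:
        cv = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        y_pred = cross_val_predict(clf, features, labels, cv=cv)
        y_true = labels
    else:
        x_tr, x_te, y_tr, y_true = train_test_split(
            features, labels, test_size=test_size, stratify=labels,
            random_state=seed,
        )
        clf.fit(x_tr, y_tr)
        y_pred = clf.predict(x_te)
    if averaging == "macro":
        return _macro_report(y_true, y_pred)
    return confusion_metrics(_micro_counts(y_true, y_pred))
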