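"""Severity labeling, wrapper feature selection, linear-SVM LOOCV evaluation.

AHI (apnea-hypopnea index, events/hour) maps to four clinical severity bands:
normal [0, 5), mild [5, 15), moderate [15, 30), severe [30, inf). The model is
a linear-kernel SVM (pairwise one-vs-one multi-class, min-max scaled inputs)
over a wrapper-selected feature subset; evaluation is leave-one-out
cross-validation accumulated into a 4x4 confusion matrix, from which per-class
and binary screening metrics are derived.

Feature selection is a two-stage wrapper with linear forward search: each
feature is first ranked by the stratified m-fold CV accuracy of a
single-feature linear SVM, then a greedy forward pass over the top-k ranked
features grows the subset while the subset's CV accuracy improves.

Selection may run once on the full cohort (the workflow the published
numbers imply — optimistic, since the held-out subject influenced the
subset) or nested inside every LOOCV fold (leakage-free). Both modes are
provided; the pooled mode is the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: severity classes in canonical (increasing) order
SEVERITIES = ("normal", "mild", "moderate", "severe")

#: AHI band lower edges (events/hour); bands are half-open
_AHI_EDGES = (0.0, 5.0, 15.0, 30.0)


def ahi_to_severity(ahi: float) -> str:
    """Map an AHI value to its severity band: [0,5) [5,15) [15,30) [30,inf)."""
    if ahi < 0:
        raise ValidationError(f"AHI must be non-negative, got {ahi}")
    if ahi < 5:
        return "normal"
    if ahi < 15:
        return "mild"
    if ahi < 30:
        return "moderate"
    return "severe"


@dataclass
class SelectionResult:
    """Outcome of wrapper selection: the full ranking and the chosen subset."""

    ranked_features: list[tuple[str, float]]   # (name, single-feature CV accuracy)
    selected: list[str]
    cv_score: float                            # CV accuracy of the final subset
    k: int
    folds: int
    seed: int


@dataclass
class ConfusionMatrix:
    """4x4 counts; rows = true class, columns = predicted, severity order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4):
            raise ValidationError("confusion matrix must be 4x4")
        if np.any(self.counts < 0):
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Per-class and aggregate classification metrics (fractions in [0, 1])."""

    per_class: dict[str, dict[str, float]]
    accuracy: float
    weighted: dict[str, float]
    zero_denominator_flags: list[str] = field(default_factory=list)


@dataclass
class BinaryMetrics:
    """Normal-vs-OSA screening metrics derived from the 4x4 matrix."""

    sensitivity: float
    specificity: float
    accuracy: float
    tp: int
    tn: int
    fp: int
    fn: int


def _make_svm(C: float = 1.0) -> Pipeline:
    # min-max scaling to [0,1] fit on training data only; OvO is SVC's default.
    # Balanced class weights keep the pairwise machines honest under the
    # one-subject-short imbalance every LOOCV training fold has — without
    # them a weakly regularized pair degenerates into majority voting against
    # the held-out subject's class.
    return Pipeline([
        ("scale", MinMaxScaler()),
        ("svm", SVC(kernel="linear", C=C, class_weight="balanced",
                    decision_function_shape="ovo")),
    ])


def train_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> Pipeline:
    """Fit a min-max-scaled linear SVM (pairwise one-vs-one multi-class)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("training requires at least two classes")
    clf = _make_svm(C)
    clf.fit(np.asarray(X, dtype=np.float64), y)
    return clf


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, folds: int, seed: int, C: float
) -> float:
    """Stratified m-fold CV accuracy of the linear SVM on the given columns."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        clf = _make_svm(C)
        clf.fit(X[train_idx], y[train_idx])
        correct += int((clf.predict(X[test_idx]) == y[test_idx]).sum())
    return correct / len(y)


def select_features(
    X: pd.DataFrame,
    y: np.ndarray,
    k: int = 50,
    folds: int = 5,
    seed: int = 0,
    C: float = 1.0,
) -> SelectionResult:
    """Wrapper feature selection with linear forward search.

    Stage 1 ranks every feature by the stratified ``folds``-fold CV accuracy
    of a linear SVM trained on that feature alone. Stage 2 greedily grows a
    subset from the top-``k`` ranked features, adding the feature that most
    improves the subset's CV accuracy and stopping when no addition improves
    it. Ties break toward the lower-ranked (earlier) feature, so the result
    is deterministic under a fixed seed.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("selection requires at least two classes")
    _, class_counts = np.unique(y, return_counts=True)
    if class_counts.min() < folds:
        raise ValidationError(
            f"every class needs >= {folds} subjects for {folds}-fold CV"
        )
    names = list(X.columns)
    k = min(k, len(names))
    Xv = X.to_numpy(dtype=np.float64)

    scores = [
        _cv_accuracy(Xv[:, [j]], y, folds, seed, C) for j in range(len(names))
    ]
    order = sorted(range(len(names)), key=lambda j: (-scores[j], j))
    ranked = [(names[j], scores[j]) for j in order]
    top = order[:k]

    selected: list[int] = []
    best_score = -np.inf
    while True:
        best_candidate, best_candidate_score = None, best_score
        for j in top:
            if j in selected:
                continue
            s = _cv_accuracy(Xv[:, selected + [j]], y, folds, seed, C)
            if s > best_candidate_score:
                best_candidate, best_candidate_score = j, s
        if best_candidate is None:
            break
        selected.append(best_candidate)
        best_score = best_candidate_score
    return SelectionResult(
        ranked_features=ranked,
        selected=[names[j] for j in selected],
        cv_score=float(best_score),
        k=k,
        folds=folds,
        seed=seed,
    )


def loocv_evaluate(
    X: pd.DataFrame,
    y: np.ndarray,
    C: float = 1.0,
    nested: bool = False,
    k: int = 50,
    folds: int = 5,
    seed: int = 0,
) -> ConfusionMatrix:
    """Leave-one-out cross-validation accumulated into a 4x4 confusion matrix.

    With ``nested=True`` feature selection is redone inside every fold on the
    n-1 training subjects (leakage-free); otherwise ``X`` is used as given
    (typically already restricted to a pooled-selection subset). Scaling and
    SVM training always see only the training fold.
    """
    y = np.asarray(y)
    n = len(y)
    n_classes = len(np.unique(y))
    if n < n_classes + 1:
        raise ValidationError("LOOCV needs more subjects than classes")
    cm = np.zeros((4, 4), dtype=np.int64)
    cls_index = {c: i for i, c in enumerate(SEVERITIES)}
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_train, y_train = X.iloc[mask], y[mask]
        if len(np.unique(y_train)) < n_classes:
            logger.warning("LOOCV fold %d is missing a class; evaluating anyway", i)
        if nested:
            sel = select_features(X_train, y_train, k=k, folds=folds, seed=seed, C=C)
            cols = sel.selected
        else:
            cols = list(X.columns)
        clf = train_svm(X_train[cols].to_numpy(), y_train, C=C)
        pred = clf.predict(X.iloc[[i]][cols].to_numpy())[0]
        cm[cls_index[y[i]], cls_index[pred]] += 1
    return ConfusionMatrix(counts=cm)


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class TP/FP rate, precision, recall, F-measure; overall accuracy.

    Weighted averages use class sizes (row sums) as weights, so weighted
    recall equals accuracy. Cells with a zero denominator are reported as 0
    and flagged.
    """
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValidationError("empty confusion matrix")
    flags: list[str] = []
    per_class: dict[str, dict[str, float]] = {}

    def safe_div(num: float, den: float, label: str) -> float:
        if den == 0:
            flags.append(label)
            return 0.0
        return num / den

    for i, name in enumerate(SEVERITIES):
        row = counts[i].sum()
        col = counts[:, i].sum()
        tp = counts[i, i]
        tp_rate = safe_div(tp, row, f"{name}.tp_rate")
        fp_rate = safe_div(col - tp, total - row, f"{name}.fp_rate")
        precision = safe_div(tp, col, f"{name}.precision")
        recall = tp_rate
        f_measure = safe_div(2 * precision * recall, precision + recall,
                             f"{name}.f_measure")
        per_class[name] = {
            "tp_rate": tp_rate,
            "fp_rate": fp_rate,
            "precision": precision,
            "recall": recall,
            "f_measure": f_measure,
        }
    weights = counts.sum(axis=1) / total
    weighted = {
        metric: float(sum(weights[i] * per_class[name][metric]
                          for i, name in enumerate(SEVERITIES)))
        for metric in ("tp_rate", "fp_rate", "precision", "recall", "f_measure")
    }
    return MetricsReport(
        per_class=per_class,
        accuracy=float(np.trace(counts) / total),
        weighted=weighted,
        zero_denominator_flags=flags,
    )


def export_model_bundle(
    clf: Pipeline,
    feature_names: list[str],
    config: dict | None = None,
    seed: int | None = None,
) -> dict:
    """JSON-serializable bundle of a fitted model.

    Captures the selected feature names, the min-max scaler ranges, the
    per-pair linear weight vectors and biases of the one-vs-one SVM, and the
    run's config snapshot and seed — enough to re-apply the model without
    pickling.
    """
    scaler: MinMaxScaler = clf.named_steps["scale"]
    svm: SVC = clf.named_steps["svm"]
    return {
        "feature_names": list(feature_names),
        "scaler": {
            "data_min": scaler.data_min_.tolist(),
            "data_max": scaler.data_max_.tolist(),
        },
        "classes": [str(c) for c in svm.classes_],
        "pairwise_weights": svm.coef_.tolist(),
        "pairwise_biases": svm.intercept_.tolist(),
        "C": svm.C,
        "config": config,
        "seed": seed,
    }


def binarize_confusion(cm: ConfusionMatrix) -> BinaryMetrics:
    """Collapse the 4x4 matrix to normal-vs-OSA screening metrics.

    Positive = any OSA class (mild/moderate/severe); a prediction is positive
    iff the predicted class is not normal. This follows the class labels, not
    the raw AHI threshold, matching how a 4-class screen would be used.
    """
    c = cm.counts
    tn = int(c[0, 0])
    fp = int(c[0, 1:].sum())
    fn = int(c[1:, 0].sum())
    tp = int(c[1:, 1:].sum())
    total = tn + fp + fn + tp
    return BinaryMetrics(
        sensitivity=tp / (tp + fn) if tp + fn else 0.0,
        specificity=tn / (tn + fp) if tn + fp else 0.0,
        accuracy=(tp + tn) / total if total else 0.0,
        tp=tp, tn=tn, fp=fp, fn=fn,
    )
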