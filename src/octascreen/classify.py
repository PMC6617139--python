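"""Hierarchical multi-task SVM classification with ROC/AUC reporting.

Four tasks are arranged as a decision hierarchy: (1) control vs. disease,
(2) among diseased eyes, diabetic (DR) vs. sickle-cell (SCR) retinopathy,
and (3) severity staging within each branch (3-class NPDR, 2-class SCR).
Each stage is a support vector machine trained on that stage's optimal
feature subset; performance is measured with pooled out-of-fold
predictions from stratified, subject-grouped 5-fold cross-validation:
sensitivity, specificity, accuracy (percent), the ROC curve and its
trapezoidal AUC (equivalently the Mann-Whitney probability that a random
positive outscores a random negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import TASKS, TaskSpec, _folds_iter, task_frame


def _make_svm(kernel: str = "linear", C: float = 10.0) -> object:
    """Linear SVM with class-balanced weights behind a train-fold scaler.

    With at most a handful of features and small cohorts, the linear
    kernel is the lowest-variance choice.  C defaults to 10: quantitative
    retinal features can separate groups by gaps that are narrow relative
    to the within-class spread, and a heavily regularized margin parks the
    boundary inside the nearer class; C=10 keeps the boundary in the gap
    while leaving chance-level data at chance.  Both knobs are exposed.
    """
    return make_pipeline(
        StandardScaler(),
        SVC(kernel=kernel, C=C, class_weight="balanced",
            decision_function_shape="ovr"),
    )


# ---------------------------------------------------------------------------
# metrics


def compute_metrics(truth, predicted, positive_class=1):
    """Sensitivity, specificity and accuracy in percent.

    Binary: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).  With
    more than two classes, per-class one-vs-rest values are macro-averaged
    over the classes present in the truth; absent classes are skipped with
    a warning.
    """
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.size == 0 or t.size != p.size:
        raise ValueError("truth and predictions must be nonempty and aligned")
    classes = np.unique(np.concatenate([t, p]))
    accuracy = 100.0 * float((t == p).mean())
    if len(classes) <= 2:
        pos = positive_class
        tp = int(((t == pos) & (p == pos)).sum())
        fn = int(((t == pos) & (p != pos)).sum())
        tn = int(((t != pos) & (p != pos)).sum())
        fp = int(((t != pos) & (p == pos)).sum())
        sens = 100.0 * tp / (tp + fn) if tp + fn else np.nan
        spec = 100.0 * tn / (tn + fp) if tn + fp else np.nan
        return sens, spec, accuracy
    sens_list, spec_list = [], []
    for c in classes:
        if not (t == c).any():
            warnings.warn(f"class {c} absent from truth; skipped in macro "
                          "average", stacklevel=2)
            continue
        s, sp, _ = compute_metrics((t == c).astype(int), (p == c).astype(int))
        sens_list.append(s)
        spec_list.append(sp)
    return float(np.mean(sens_list)), float(np.mean(spec_list)), accuracy


def roc_curve_auc(scores, truth):
    """ROC points and trapezoidal AUC from continuous scores.

    Thresholds sweep the unique scores from high to low; tied scores move
    the operating point diagonally, so the trapezoidal area equals the
    Mann-Whitney statistic with ties counted one half.  Constant scores
    give the chance diagonal (AUC 0.5) with a warning.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    if np.ptp(s) == 0:
        warnings.warn("constant scores: degenerate single-point ROC",
                      stacklevel=2)
        return np.array([[0.0, 0.0], [1.0, 1.0]]), 0.5
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied-score run
    last = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[last] / n_pos]
    fpr = np.r_[0.0, fps[last] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def _macro_ovr_auc(scores: np.ndarray, truth: np.ndarray):
    """Macro-averaged one-vs-rest AUC for multi-class decision scores."""
    classes = np.unique(truth)
    aucs = []
    curves = {}
    for i, c in enumerate(classes):
        col = scores[:, i] if scores.ndim == 2 else scores
        roc, auc = roc_curve_auc(col, (truth == c).astype(int))
        curves[int(c)] = roc
        aucs.append(auc)
    return curves, float(np.mean(aucs))


# ---------------------------------------------------------------------------
# cross-validated task training


@dataclass
class ClassifierReport:
    """Cross-validated performance of one task."""

    task_id: str
    feature_subset: list[str]
    fold_assignments: np.ndarray
    truth: np.ndarray
    predictions: np.ndarray
    scores: np.ndarray
    sensitivity: float
    specificity: float
    accuracy: float
    roc_points: np.ndarray | dict
    auc: float
    per_fold_accuracy: list[float] = field(default_factory=list)
    n_folds: int = 5

    def to_dict(self) -> dict:
        roc = self.roc_points
        if isinstance(roc, dict):
            roc = {str(k): v.tolist() for k, v in roc.items()}
        else:
            roc = roc.tolist()
        return {
            "task_id": self.task_id,
            "feature_subset": self.feature_subset,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "per_fold_accuracy": self.per_fold_accuracy,
            "n_folds": self.n_folds,
        }


def train_task(
    cohort: pd.DataFrame,
    task: TaskSpec,
    features: list[str],
    folds: int = 5,
    seed: int = 0,
    kernel: str = "linear",
    group_by_subject: bool = True,
) -> ClassifierReport:
    """Cross-validate an SVM on one task and pool out-of-fold predictions.

    Folds are stratified by class and grouped by subject so both eyes of
    one subject never straddle a train/test split.  Metrics come from the
    single pooled confusion matrix; per-fold accuracies are logged too.
    """
    if not features:
        raise ValueError("features must be nonempty")
    X, y, sub = task_frame(cohort, task, features)
    Xv, yv = X.to_numpy(dtype=float), y.to_numpy()
    classes = np.unique(yv)
    if len(classes) < 2:
        raise ValueError("cohort contains a single class")
    counts = np.bincount(yv)
    n_folds = folds
    if counts[counts > 0].min() < folds:
        n_folds = max(2, int(counts[counts > 0].min()))
        warnings.warn(f"class with fewer members than folds: using "
                      f"{n_folds} folds", stacklevel=2)
    groups = sub["subject_id"].to_numpy() if (
        group_by_subject and "subject_id" in sub) else None

    preds = np.empty_like(yv)
    n_score_cols = len(classes) if len(classes) > 2 else 1
    scores = np.zeros((len(yv), n_score_cols))
    fold_of = np.full(len(yv), -1)
    per_fold = []
    for k, (tr, te) in enumerate(_folds_iter(yv, groups, n_folds, seed)):
        clf = _make_svm(kernel)
        clf.fit(Xv[tr], yv[tr])
        preds[te] = clf.predict(Xv[te])
        df = clf.decision_function(Xv[te])
        scores[te] = df.reshape(len(te), -1) if len(classes) > 2 else \
            np.asarray(df).reshape(-1, 1)
        fold_of[te] = k
        per_fold.append(100.0 * float((preds[te] == yv[te]).mean()))

    sens, spec, acc = compute_metrics(yv, preds)
    if len(classes) == 2:
        roc, auc = roc_curve_auc(scores[:, 0], yv)
    else:
        roc, auc = _macro_ovr_auc(scores, yv)
    return ClassifierReport(
        task_id=task.task_id,
        feature_subset=list(features),
        fold_assignments=fold_of,
        truth=yv,
        predictions=preds,
        scores=scores,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        roc_points=roc,
        auc=auc,
        per_fold_accuracy=per_fold,
        n_folds=n_folds,
    )


# ---------------------------------------------------------------------------
# hierarchy


STAGE_ORDER = ("control_vs_disease", "dr_vs_scr", "npdr_staging", "scr_staging")

#: leaf label per (task, predicted class) used when routing
_LEAVES = {
    ("npdr_staging", 0): "mild_npdr",
    ("npdr_staging", 1): "moderate_npdr",
    ("npdr_staging", 2): "severe_npdr",
    ("scr_staging", 0): "mild_scr",
    ("scr_staging", 1): "severe_scr",
}


@dataclass
class HierarchicalModel:
    """Stage SVMs plus routing: control gate, disease split, staging."""

    models: dict  # task_id -> fitted pipeline
    feature_subsets: dict  # task_id -> list of features

    def predict_row(self, row: pd.Series) -> str:
        def score(task_id):
            X = np.asarray(
                [row[f] for f in self.feature_subsets[task_id]], dtype=float
            ).reshape(1, -1)
            return int(self.models[task_id].predict(X)[0])

        if score("control_vs_disease") == 0:
            return "control"
        branch = "npdr_staging" if score("dr_vs_scr") == 0 else "scr_staging"
        return _LEAVES[(branch, score(branch))]

    def predict(self, cohort: pd.DataFrame) -> pd.Series:
        return cohort.apply(self.predict_row, axis=1)


def assemble_hierarchy(
    cohort: pd.DataFrame,
    feature_subsets: dict[str, list[str]],
    kernel: str = "linear",
) -> HierarchicalModel:
    """Fit all four stage models on their true sub-cohorts.

    ``feature_subsets`` maps each task id to its retained feature list
    (from backward elimination); a missing stage raises a validation
    error naming it.
    """
    missing = [t for t in STAGE_ORDER if t not in feature_subsets
               or not feature_subsets[t]]
    if missing:
        raise ValueError(f"missing stage feature subsets: {missing}")
    models = {}
    for task_id in STAGE_ORDER:
        task = TASKS[task_id]
        X, y, _ = task_frame(cohort, task, feature_subsets[task_id])
        clf = _make_svm(kernel)
        clf.fit(X.to_numpy(dtype=float), y.to_numpy())
        models[task_id] = clf
    return HierarchicalModel(models=models, feature_subsets=dict(feature_subsets))


def evaluate_hierarchy_end_to_end(
    model: HierarchicalModel, cohort: pd.DataFrame
) -> dict:
    """Leaf-label accuracy of the full routing chain, with per-stage rates."""
    pred = model.predict(cohort)
    truth = cohort["label"]
    out = {"leaf_accuracy": 100.0 * float((pred == truth).mean())}
    disease = truth != "control"
    out["stage1_accuracy"] = 100.0 * float(
        ((pred != "control") == disease).mean())
    return out
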