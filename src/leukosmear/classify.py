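"""Supervised classification of acute-leukemia families and subtypes.

Six tasks are evaluated under stratified 10-fold cross-validation: the
family split (ALL vs AML), the lymphoblastic split (L1 vs L2), three
one-vs-rest myeloblastic splits (M2, M3, M5 against the other two) and the
three-way myeloblastic task.  The learner roster mirrors the classical
instance-based / tree / regression / committee mix: 1-nearest-neighbor,
random forest, logistic regression, linear-kernel SVM and an
extremely-randomized-tree committee.  Reports carry overall accuracy, TPR,
TNR and ROC AUC (macro-averaged / one-vs-rest for the multiclass task),
plus per-fold confusion matrices from which the metrics recompute exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "TaskSpec",
    "TASKS",
    "EvalReport",
    "make_learner",
    "build_task_dataset",
    "train_and_crossvalidate",
    "compare_feature_subsets",
]


@dataclass(frozen=True)
class TaskSpec:
    """One classification task: which labels map to which classes."""

    name: str
    class_map: dict[str, str]  # raw label -> task class
    n_classes: int

    def positive_class(self) -> str | None:
        """The designated positive class of a binary task (None for multiclass)."""
        if self.n_classes != 2:
            return None
        # one-vs-rest tasks name the positive class before 'vs'
        return self.name.split("vs")[0]


def _binary(name: str, positives: list[str], negatives: list[str], neg_name: str) -> TaskSpec:
    cmap = {p: name.split("vs")[0] for p in positives}
    cmap.update({n: neg_name for n in negatives})
    return TaskSpec(name=name, class_map=cmap, n_classes=2)


TASKS: dict[str, TaskSpec] = {
    "ALLvsAML": TaskSpec(
        "ALLvsAML",
        {"L1": "ALL", "L2": "ALL", "M2": "AML", "M3": "AML", "M5": "AML"},
        2,
    ),
    "L1vsL2": TaskSpec("L1vsL2", {"L1": "L1", "L2": "L2"}, 2),
    "M2vs(M3&M5)": _binary("M2vs(M3&M5)", ["M2"], ["M3", "M5"], "M3&M5"),
    "M3vs(M2&M5)": _binary("M3vs(M2&M5)", ["M3"], ["M2", "M5"], "M2&M5"),
    "M5vs(M2&M3)": _binary("M5vs(M2&M3)", ["M5"], ["M2", "M3"], "M2&M3"),
    "M2vsM3vsM5": TaskSpec("M2vsM3vsM5", {"M2": "M2", "M3": "M3", "M5": "M5"}, 3),
}

#: column-prefix definitions of the two feature subsets compared in the study:
#: nucleus+cytoplasm ('nc', the proposed description) vs whole-cell-only ('c')
SUBSET_PREFIXES = {"nc": ("nucleus_", "cytoplasm_", "n_"), "c": ("cell_",)}


@dataclass
class EvalReport:
    """Cross-validated evaluation of one learner on one task."""

    task: str
    learner: str
    accuracy: float  # percent
    tpr: float
    tnr: float
    auc: float
    confusion: np.ndarray  # pooled over folds, rows = true classes
    fold_confusions: list[np.ndarray] = field(default_factory=list)
    classes: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "task": self.task,
            "learner": self.learner,
            "accuracy_pct": self.accuracy,
            "TPR": self.tpr,
            "TNR": self.tnr,
            "AUC": self.auc,
        }


def make_learner(name: str, seed: int = 0):
    """Instantiate a roster learner by identifier."""
    seed = int(seed) % (2**31)
    if name == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=1))
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "logistic":
        return make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
    if name == "svm":
        return make_pipeline(StandardScaler(), SVC(kernel="linear", random_state=seed))
    if name == "rc":
        return ExtraTreesClassifier(n_estimators=100, random_state=seed)
    raise ValueError(f"unknown learner {name!r}")


def build_task_dataset(
    table: pd.DataFrame, task: TaskSpec, subset: str | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Map a labeled feature table onto a task's classes.

    Rows whose label does not participate in the task (including any
    'No subtype' rows) are dropped; ``subset`` filters columns to the
    nucleus+cytoplasm ('nc') or whole-cell ('c') description.

    Raises
    ------
    ValueError : when a task class has no samples or the subset matches no
        columns.
    """
    if "label" not in table.columns:
        raise ValueError("feature table must carry a 'label' column")
    keep = table["label"].isin(task.class_map)
    sub = table.loc[keep]
    y = sub["label"].map(task.class_map)
    present = set(y.unique())
    wanted = set(task.class_map.values())
    if present != wanted:
        raise ValueError(f"task {task.name}: classes {sorted(wanted - present)} absent from table")
    X = sub.drop(columns=["label"])
    if subset is not None:
        prefixes = SUBSET_PREFIXES[subset]
        cols = [c for c in X.columns if c.startswith(prefixes)]
        if not cols:
            raise ValueError(f"subset {subset!r} matches no columns")
        X = X[cols]
    return X, y


def _scores(model, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Continuous per-class scores for AUC (probability, margin, or distance)."""
    final = model.steps[-1][1] if hasattr(model, "steps") else model
    if isinstance(final, KNeighborsClassifier):
        # inverse-distance score to the nearest training point of each class
        Xq = model[:-1].transform(X) if hasattr(model, "steps") else X
        Xt = final._fit_X
        y_train = final._y
        s = np.empty((len(Xq), len(classes)))
        for ci in range(len(classes)):
            pts = Xt[y_train == ci]
            d = np.sqrt(((Xq[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
            s[:, ci] = 1.0 / (1e-9 + d)
        return s / s.sum(axis=1, keepdims=True)
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)
    df = model.decision_function(X)
    if df.ndim == 1:
        return np.column_stack([-df, df])
    return df


def train_and_crossvalidate(
    X: pd.DataFrame,
    y: pd.Series,
    learner: str = "rf",
    folds: int = 10,
    seed: int = 0,
    positive: str | None = None,
) -> EvalReport:
    """Stratified k-fold cross-validation with pooled metrics.

    Predictions are pooled over folds; accuracy is the overall percentage of
    correct classifications.  For binary tasks TPR/TNR are the recalls of
    the ``positive`` class and its complement (default positive = second
    class in sorted order); for multiclass they are macro-averaged per-class
    recall/specificity and the AUC is one-vs-rest averaged.  The seed fixes
    fold assignment and any stochastic learner.

    Raises
    ------
    ValueError : when some class has fewer members than ``folds``.
    """
    X = np.asarray(X, dtype=np.float64) if not isinstance(X, pd.DataFrame) else X.to_numpy(dtype=np.float64)
    y = pd.Series(y).reset_index(drop=True)
    classes = np.array(sorted(y.unique()))
    counts = y.value_counts()
    if counts.min() < folds:
        raise ValueError(
            f"class {counts.idxmin()!r} has {counts.min()} samples < {folds} folds; use fewer folds"
        )
    y_idx = y.map({c: i for i, c in enumerate(classes)}).to_numpy()

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    pooled_pred = np.empty(len(y), dtype=np.int64)
    pooled_scores = np.empty((len(y), len(classes)))
    fold_confusions = []
    for train_idx, test_idx in skf.split(X, y_idx):
        model = make_learner(learner, seed=seed)
        model.fit(X[train_idx], y_idx[train_idx])
        pred = model.predict(X[test_idx])
        pooled_pred[test_idx] = pred
        pooled_scores[test_idx] = _scores(model, X[test_idx], classes)
        fold_confusions.append(confusion_matrix(y_idx[test_idx], pred, labels=range(len(classes))))

    conf = confusion_matrix(y_idx, pooled_pred, labels=range(len(classes)))
    accuracy = 100.0 * np.trace(conf) / conf.sum()
    if len(classes) == 2:
        pos = 1 if positive is None else int(np.nonzero(classes == positive)[0][0])
        neg = 1 - pos
        tp = conf[pos, pos]
        fn = conf[pos, neg]
        tn = conf[neg, neg]
        fp = conf[neg, pos]
        tpr = tp / (tp + fn)
        tnr = tn / (tn + fp)
        auc = float(roc_auc_score((y_idx == pos).astype(int), pooled_scores[:, pos]))
    else:
        recalls, specs = [], []
        for c in range(len(classes)):
            tp = conf[c, c]
            fn = conf[c].sum() - tp
            fp = conf[:, c].sum() - tp
            tn = conf.sum() - tp - fn - fp
            recalls.append(tp / (tp + fn))
            specs.append(tn / (tn + fp))
        tpr = float(np.mean(recalls))
        tnr = float(np.mean(specs))
        auc = float(roc_auc_score(y_idx, pooled_scores, multi_class="ovr", average="macro"))
    return EvalReport(
        task="",
        learner=learner,
        accuracy=float(accuracy),
        tpr=float(tpr),
        tnr=float(tnr),
        auc=auc,
        confusion=conf,
        fold_confusions=fold_confusions,
        classes=list(classes),
    )


def compare_feature_subsets(
    table: pd.DataFrame,
    task: TaskSpec,
    learner: str = "rf",
    folds: int = 10,
    seed: int = 0,
) -> dict:
    """Evaluate the nucleus+cytoplasm vs whole-cell-only feature subsets.

    Both runs share the same fold assignment (same seed on the same rows) so
    the accuracy difference is a paired comparison.
    """
    results = {}
    for subset in ("nc", "c"):
        X, y = build_task_dataset(table, task, subset=subset)
        report = train_and_crossvalidate(
            X, y, learner=learner, folds=folds, seed=seed, positive=task.positive_class()
        )
        report.task = task.name
        results[subset] = report
    results["accuracy_difference"] = results["nc"].accuracy - results["c"].accuracy
    return results
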