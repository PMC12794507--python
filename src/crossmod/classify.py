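"""Disease-vs-healthy classification with module genes vs control genes.

Evaluates whether a gene set carries disease-discriminative signal: features
are the expression of the set's genes across samples, the model is
L2-regularized logistic regression under repeated stratified k-fold
cross-validation, and the metrics are the F1 score of the disease class and
Cohen's chance-corrected kappa, computed on the pooled out-of-fold
predictions of each repeat and averaged over repeats.  A matched-size set of
CV²-selected highly variable genes serves as the control feature set.

Standardization parameters are estimated on training folds only — the
classic leakage trap with cross-sample z-scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import cohen_kappa_score, confusion_matrix, f1_score
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.preprocessing import StandardScaler

from .discovery import select_overdispersed
from .io_core import CountMatrix, GeneSet


@dataclass
class CVPlan:
    k_folds: int = 5
    repeats: int = 10
    seed: int = 0
    C: float = 1.0      # inverse L2 penalty; fixed small-ish for stability

    def validate(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class ClassifierReport:
    f1: float
    kappa: float
    per_repeat: pd.DataFrame
    per_fold: pd.DataFrame
    feature_set: str = ""
    group: str = ""
    confusion: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))


def cv2_select(counts: CountMatrix, n_genes: int) -> GeneSet:
    """Top ``n_genes`` by CV² deviation significance (control feature set).

    Shares the overdispersion fit machinery of the discovery stage;
    ``n_genes`` conventionally equals the module size so the two feature
    sets are matched in dimension.
    """
    gs, _ = select_overdispersed(counts, n_genes)
    return GeneSet("cv2_control", gs.genes)


def evaluate_classifier(features: pd.DataFrame, labels: pd.Series,
                        plan: CVPlan | None = None,
                        positive_label: str = "disease",
                        feature_set: str = "", group: str = ""
                        ) -> ClassifierReport:
    """Repeated stratified CV of a logistic classifier on the features.

    ``features`` is samples × genes; ``labels`` has two classes with the
    positive (disease) class named by ``positive_label``.  F1 and kappa are
    computed on the pooled out-of-fold predictions of each repeat and
    averaged across repeats.
    """
    plan = plan or CVPlan()
    plan.validate()
    labels = labels.loc[features.index]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} not in {classes}")
    y = (labels == positive_label).astype(int).to_numpy()
    if min(np.bincount(y)) < plan.k_folds:
        raise ValueError(
            "a class has fewer samples than k_folds; reduce k_folds"
        )
    X = features.to_numpy(dtype=float)

    cv = RepeatedStratifiedKFold(n_splits=plan.k_folds,
                                 n_repeats=plan.repeats,
                                 random_state=plan.seed)
    fold_rows = []
    pooled_true: dict[int, list[np.ndarray]] = {r: [] for r in range(plan.repeats)}
    pooled_pred: dict[int, list[np.ndarray]] = {r: [] for r in range(plan.repeats)}
    for i, (train, test) in enumerate(cv.split(X, y)):
        repeat, fold = divmod(i, plan.k_folds)
        if len(np.unique(y[train])) < 2:
            raise ValueError("single-class training fold; reduce k_folds")
        scaler = StandardScaler().fit(X[train])
        clf = LogisticRegression(penalty="l2", C=plan.C, max_iter=1000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(scaler.transform(X[train]), y[train])
        pred = clf.predict(scaler.transform(X[test]))
        pooled_true[repeat].append(y[test])
        pooled_pred[repeat].append(pred)
        fold_rows.append({
            "repeat": repeat, "fold": fold,
            "f1": f1_score(y[test], pred, zero_division=0),
            "kappa": cohen_kappa_score(y[test], pred)
            if len(np.unique(pred)) > 1 or len(np.unique(y[test])) > 1 else 0.0,
        })

    repeat_rows = []
    total_conf = np.zeros((2, 2))
    for r in range(plan.repeats):
        yt = np.concatenate(pooled_true[r])
        yp = np.concatenate(pooled_pred[r])
        repeat_rows.append({
            "repeat": r,
            "f1": f1_score(yt, yp, zero_division=0),
            "kappa": cohen_kappa_score(yt, yp),
        })
        total_conf += confusion_matrix(yt, yp, labels=[0, 1])
    per_repeat = pd.DataFrame(repeat_rows)
    kappas = per_repeat["kappa"].to_numpy()
    return ClassifierReport(
        f1=float(per_repeat["f1"].mean()),
        kappa=float(np.nan_to_num(kappas, nan=0.0).mean()),
        per_repeat=per_repeat,
        per_fold=pd.DataFrame(fold_rows),
        feature_set=feature_set, group=group,
        confusion=total_conf,
    )


def compare_feature_sets(
    expr: pd.DataFrame, labels: pd.Series,
    feature_sets: dict[str, GeneSet], plan: CVPlan | None = None,
    positive_label: str = "disease", group: str = "",
    min_samples_factor: int = 2,
) -> pd.DataFrame:
    """One classification run per feature set; mirrors a per-group report.

    ``expr`` is samples × genes.  Groups with fewer than
    ``min_samples_factor · k_folds`` samples are skipped with a warning.
    """
    plan = plan or CVPlan()
    if len(expr) < min_samples_factor * plan.k_folds:
        warnings.warn(f"group {group!r} has too few samples; skipped",
                      stacklevel=2)
        return pd.DataFrame()
    rows = []
    for name, gs in feature_sets.items():
        genes = [g for g in gs.genes if g in expr.columns]
        if not genes:
            warnings.warn(f"feature set {name!r} has no genes in the data; "
                          "skipped", stacklevel=2)
            continue
        report = evaluate_classifier(expr[genes], labels, plan,
                                     positive_label=positive_label,
                                     feature_set=name, group=group)
        rows.append({"group": group, "feature_set": name,
                     "n_features": len(genes),
                     "f1": report.f1, "kappa": report.kappa})
    return pd.DataFrame(rows)
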