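"""One-vs-rest characterization of the final groups.

Each final group is contrasted against the union of the others: Wilcoxon
rank-sum p-values (two-sided, unpaired) and log2 fold changes of group
means for every clinical factor and molecule; random-forest
(mean-decrease-impurity) importances rank features by how well they
separate the groups; and a leave-one-out support-vector-machine evaluation
measures how well named feature sets predict group membership (ROC/AUC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as sk_auc, roc_curve
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


def one_vs_rest_contrasts(features: pd.DataFrame, group_labels: pd.Series
                          ) -> pd.DataFrame:
    """Wilcoxon rank-sum contrasts of each group vs the rest.

    ``features`` has features as rows and samples as columns; every column
    must be labeled.  Returns one record per (feature, group) with the
    two-sided p (exact where sample sizes permit, normal approximation with
    tie correction otherwise) and log2(mean group / mean rest); the fold
    change is NaN when the rest mean is not positive.
    """
    groups = sorted(group_labels.unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    x = features.loc[:, group_labels.index]
    records = []
    for g in groups:
        in_g = (group_labels == g).to_numpy()
        if in_g.sum() < 2 or (~in_g).sum() < 2:
            raise ValueError(f"group {g} or its complement has < 2 samples")
        a = x.loc[:, in_g].to_numpy()
        b = x.loc[:, ~in_g].to_numpy()
        for i, feat in enumerate(x.index):
            if np.all(a[i] == a[i][0]) and np.all(b[i] == a[i][0]):
                p = 1.0
            else:
                p = float(mannwhitneyu(a[i], b[i], alternative="two-sided",
                                       method="auto").pvalue)
            mg, mr = float(np.mean(a[i])), float(np.mean(b[i]))
            if mr <= 0 or mg <= 0:
                lfc = np.nan
            else:
                lfc = float(np.log2(mg / mr))
            records.append((feat, g, p, lfc))
    out = pd.DataFrame(records, columns=["feature", "group", "p_value",
                                         "log2fc"])
    n_undef = int(out["log2fc"].isna().sum())
    if n_undef:
        logger.warning("one_vs_rest_contrasts: %d fold change(s) undefined "
                       "(non-positive mean)", n_undef)
    return out


def rf_importance(features: pd.DataFrame, group_labels: pd.Series,
                  n_trees: int = 1000, seed: int = 0) -> pd.Series:
    """Mean-decrease-impurity feature importances from a seeded forest.

    1000 trees, sqrt(p) candidate features per split.  Constant features
    get importance 0.  Returns importances sorted descending.
    """
    if group_labels.nunique() < 2:
        raise ValueError("need >= 2 groups")
    x = features.loc[:, group_labels.index].T.to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed)
    if np.all(x == x[0:1, :]):  # all-constant design: nothing to split on
        return pd.Series(0.0, index=features.index, name="importance")
    forest.fit(x, group_labels.to_numpy())
    imp = pd.Series(forest.feature_importances_, index=features.index,
                    name="importance")
    return imp.sort_values(ascending=False, kind="stable")


def top_important(importance: pd.Series, k: int = 50) -> pd.Index:
    """The top-k most important features."""
    return importance.index[:k]


@dataclass
class RocResult:
    """Held-out LOOCV scores and the resulting ROC for one feature set."""

    name: str
    scores: pd.DataFrame          # sample x class decision scores (held out)
    labels: pd.Series
    curves: dict[str, pd.DataFrame]   # class -> fpr/tpr table
    auc_per_class: dict[str, float]
    auc: float                    # macro (or micro) average


def _roc_from_scores(name: str, scores: pd.DataFrame, labels: pd.Series,
                     average: str) -> RocResult:
    classes = list(scores.columns)
    curves, aucs = {}, {}
    for c in classes:
        y = (labels == c).astype(int).to_numpy()
        fpr, tpr, _ = roc_curve(y, scores[c].to_numpy())
        curves[c] = pd.DataFrame({"fpr": fpr, "tpr": tpr,
                                  "specificity": 1 - fpr, "sensitivity": tpr})
        aucs[c] = float(sk_auc(fpr, tpr))
    if average == "macro":
        overall = float(np.mean(list(aucs.values())))
    elif average == "micro":
        y_flat = np.concatenate([(labels == c).astype(int).to_numpy()
                                 for c in classes])
        s_flat = np.concatenate([scores[c].to_numpy() for c in classes])
        fpr, tpr, _ = roc_curve(y_flat, s_flat)
        overall = float(sk_auc(fpr, tpr))
    else:
        raise ValueError(f"unknown average {average!r}")
    return RocResult(name=name, scores=scores, labels=labels, curves=curves,
                     auc_per_class=aucs, auc=overall)


def loocv_roc(features: pd.DataFrame, group_labels: pd.Series,
              feature_sets: dict[str, list[str]], C: float = 1.0,
              average: str = "macro", seed: int = 0
              ) -> dict[str, RocResult]:
    """Leave-one-out SVM evaluation of named feature sets.

    For every sample in turn, a linear-kernel maximum-margin classifier is
    trained on the remaining samples and the held-out one-vs-rest decision
    scores are recorded; each sample is predicted exactly once.  Pooled
    scores yield per-class ROC curves and a one-vs-rest AUC, macro-averaged
    by default (``average="micro"`` pools all class indicators instead).
    """
    samples = list(group_labels.index)
    y = group_labels.to_numpy()
    classes = sorted(group_labels.unique())
    counts = group_labels.value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2].tolist()
        raise ValueError(
            f"groups {small} have < 2 samples: a leave-one-out training fold "
            "would lose an entire class; use larger groups")
    results = {}
    for name, feats in feature_sets.items():
        if not feats:
            raise ValueError(f"feature set {name!r} is empty")
        x = features.loc[feats, samples].T.to_numpy()
        score_rows = np.zeros((len(samples), len(classes)))
        for i in range(len(samples)):
            train = np.ones(len(samples), dtype=bool)
            train[i] = False
            clf = SVC(kernel="linear", C=C, decision_function_shape="ovr",
                      random_state=seed)
            clf.fit(x[train], y[train])
            df = clf.decision_function(x[i:i + 1])
            if len(classes) == 2:
                # binary decision_function is signed distance for classes[1]
                score_rows[i] = np.array([-df[0], df[0]])
            else:
                order = {c: j for j, c in enumerate(clf.classes_)}
                score_rows[i] = df[0][[order[c] for c in classes]]
        scores = pd.DataFrame(score_rows, index=samples, columns=classes)
        results[name] = _roc_from_scores(name, scores, group_labels, average)
    return results
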