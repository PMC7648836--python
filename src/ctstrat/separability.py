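"""Cluster separability via cross-validated one-vs-all linear SVMs.

Discriminability of clusters (from deviation maps, or from clinical
features) is summarized by the pairwise AUROC of held-out decision values:
for each ordered class pair (i, j), the AUROC of the class-i one-vs-all
decision values over samples truly in {i, j}. Significance comes from a
label-permutation test, and feature-level interpretation from structure
coefficients (correlations between features and held-out decision values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import CVConfig


@dataclass
class OOFDecisionValues:
    """Out-of-fold one-vs-all decision values (n_samples x n_classes)."""

    values: np.ndarray
    predicted: np.ndarray
    labels: np.ndarray
    classes: np.ndarray


@dataclass
class SeparabilityReport:
    classes: np.ndarray
    auroc_matrix: np.ndarray  # k x k, symmetric, NaN diagonal
    per_cluster_auroc: np.ndarray
    grand_mean_auroc: float
    accuracy: float
    p_value: Optional[float] = None
    n_permutations: int = 0

    def to_dict(self) -> dict:
        return {
            "classes": self.classes.tolist(),
            "auroc_matrix": self.auroc_matrix.tolist(),
            "per_cluster_auroc": self.per_cluster_auroc.tolist(),
            "grand_mean_auroc": self.grand_mean_auroc,
            "accuracy": self.accuracy,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
        }


@dataclass
class StructureCoefficients:
    """Per-class feature correlations with held-out decision values.

    The p-values are for display thresholding only — decision values are
    cross-validated, so this is not a formal test.
    """

    classes: np.ndarray
    values: np.ndarray  # n_classes x n_features
    p_values: np.ndarray
    zero_variance: np.ndarray  # boolean flags per feature


def cv_ova_decision_values(features: np.ndarray, labels: np.ndarray,
                           cv_config: CVConfig | None = None,
                           seed: int = 0) -> OOFDecisionValues:
    """Stratified-CV one-vs-all linear SVM decision values.

    Features are standardized per training fold (linear SVMs are
    scale-sensitive); one binary SVM (C fixed, no inner tuning) is fit per
    class per fold and evaluated on the held-out fold. Predicted labels are
    the argmax of the per-class decision values.
    """
    cv_config = cv_config or CVConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite (impute or drop first)")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < cv_config.n_splits:
        small = classes[counts < cv_config.n_splits].tolist()
        raise ValueError(
            f"class(es) {small} have fewer members than {cv_config.n_splits} "
            "folds; reduce the fold count")
    dv = np.empty((len(y), len(classes)))
    skf = StratifiedKFold(n_splits=cv_config.n_splits, shuffle=True,
                          random_state=seed % (2 ** 31))
    for train, test in skf.split(X, y):
        scaler = StandardScaler().fit(X[train])
        X_tr, X_te = scaler.transform(X[train]), scaler.transform(X[test])
        for ci, c in enumerate(classes):
            svm = SVC(kernel="linear", C=cv_config.C)
            svm.fit(X_tr, (y[train] == c).astype(int))
            dv[test, ci] = svm.decision_function(X_te)
    predicted = classes[np.argmax(dv, axis=1)]
    return OOFDecisionValues(values=dv, predicted=predicted, labels=y,
                             classes=classes)


def _auroc(scores: np.ndarray, positive: np.ndarray) -> float:
    """Midrank (Mann-Whitney) AUROC."""
    n_pos = int(positive.sum())
    n_neg = len(positive) - n_pos
    ranks = stats.rankdata(scores)
    return float((ranks[positive].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def pairwise_auroc(dv: OOFDecisionValues) -> SeparabilityReport:
    """Pairwise AUROC matrix from one-vs-all decision values.

    Ordered entry (i, j) scores class i's decision values on samples truly
    in {i, j} with i positive; the unordered matrix averages (i, j) and
    (j, i). Per-cluster means average over partners; the grand mean averages
    the unordered upper triangle.
    """
    classes = dv.classes
    k = len(classes)
    if k < 2:
        raise ValueError("need >= 2 classes")
    ordered = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            mask = (dv.labels == classes[i]) | (dv.labels == classes[j])
            if not ((dv.labels == classes[i]).any()
                    and (dv.labels == classes[j]).any()):
                continue  # empty class: entry stays missing
            ordered[i, j] = _auroc(dv.values[mask, i],
                                   dv.labels[mask] == classes[i])
    sym = (ordered + ordered.T) / 2.0
    per_cluster = np.nanmean(sym, axis=1)
    iu = np.triu_indices(k, 1)
    grand = float(np.nanmean(sym[iu]))
    accuracy = float(np.mean(dv.predicted == dv.labels))
    return SeparabilityReport(classes=classes, auroc_matrix=sym,
                              per_cluster_auroc=per_cluster,
                              grand_mean_auroc=grand, accuracy=accuracy)


def separability_report(features: np.ndarray, labels: np.ndarray,
                        cv_config: CVConfig | None = None,
                        seed: int = 0) -> SeparabilityReport:
    """Convenience wrapper: CV decision values -> pairwise AUROC report."""
    dv = cv_ova_decision_values(features, labels, cv_config, seed)
    return pairwise_auroc(dv)


def permutation_test_separability(features: np.ndarray, labels: np.ndarray,
                                  cv_config: CVConfig | None = None,
                                  n_permutations: int = 999,
                                  seed: int = 0) -> SeparabilityReport:
    """Label-permutation test of the grand mean pairwise AUROC.

    p = (1 + #{permuted statistic >= observed}) / (n_permutations + 1),
    with the identical CV scheme recomputed per permutation.
    """
    if n_permutations < 19:
        raise ValueError("n_permutations must be >= 19")
    observed = separability_report(features, labels, cv_config, seed)
    rng = np.random.default_rng(seed)
    count = 0
    y = np.asarray(labels)
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        stat = separability_report(features, perm, cv_config,
                                   seed).grand_mean_auroc
        if stat >= observed.grand_mean_auroc:
            count += 1
    observed.p_value = (1 + count) / (n_permutations + 1)
    observed.n_permutations = n_permutations
    return observed


def structure_coefficients(features: np.ndarray,
                           dv: OOFDecisionValues) -> StructureCoefficients:
    """Pearson correlation of each feature with each class's held-out
    decision values; zero-variance features get coefficient 0 and a flag."""
    X = np.asarray(features, dtype=float)
    n, m = X.shape
    k = len(dv.classes)
    values = np.zeros((k, m))
    p_values = np.ones((k, m))
    sd_x = X.std(axis=0)
    zero_variance = sd_x == 0
    Xc = X - X.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        for ci in range(k):
            d = dv.values[:, ci]
            dc = d - d.mean()
            sd_d = d.std()
            r = (Xc.T @ dc) / (n * sd_x * sd_d) if sd_d > 0 else np.zeros(m)
            r = np.where(zero_variance, 0.0, np.clip(r, -1.0, 1.0))
            values[ci] = r
            with np.errstate(invalid="ignore", divide="ignore"):
                t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r ** 2))
            p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
            p_values[ci] = np.where(zero_variance, 1.0, p)
    return StructureCoefficients(classes=dv.classes, values=values,
                                 p_values=p_values,
                                 zero_variance=zero_variance)
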