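"""Spectral subtyping of deviation maps.

Clinical subjects' deviation Z-maps are compared by cosine similarity,
mapped to a nonnegative affinity, and partitioned by spectral clustering
(Ng-Jordan-Weiss: symmetric normalized Laplacian, k smallest eigenvectors,
row-normalized embedding, k-means with many restarts). Model order is chosen
by cross-validated mean pairwise AUROC of a one-vs-all linear SVM, and
stability is assessed by a leave-one-out re-clustering procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .config import CVConfig, derive_seeds

logger = logging.getLogger(__name__)


@dataclass
class AffinityMatrix:
    """Symmetric cosine-based affinity in [0, 1] with unit diagonal."""

    values: np.ndarray
    subject_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        A = self.values
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("affinity must be square")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("affinity must be symmetric to 1e-12")
        if A.min() < -1e-12 or A.max() > 1 + 1e-12:
            raise ValueError("affinity values must lie in [0, 1]")
        if not np.allclose(np.diag(A), 1.0):
            raise ValueError("affinity diagonal must be 1")


@dataclass
class ClusterSolution:
    k: int
    labels: np.ndarray  # 1-based
    embedding: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        used = np.unique(self.labels)
        if not np.array_equal(used, np.arange(1, self.k + 1)):
            raise ValueError(
                f"labels must use every value in 1..{self.k}; got {used}")


@dataclass
class ModelOrderReport:
    k_grid: list[int]
    mean_pairwise_auroc: list[float]  # NaN where a k was infeasible
    per_cluster_auroc: dict[int, list[float]]
    stability: dict[int, float] = field(default_factory=dict)
    selected_k: int = 0

    def to_dict(self) -> dict:
        return {
            "k_grid": self.k_grid,
            "mean_pairwise_auroc": self.mean_pairwise_auroc,
            "per_cluster_auroc": {str(k): v
                                  for k, v in self.per_cluster_auroc.items()},
            "stability": {str(k): v for k, v in self.stability.items()},
            "selected_k": self.selected_k,
        }


def cosine_affinity(z: np.ndarray,
                    subject_id: Optional[np.ndarray] = None) -> AffinityMatrix:
    """Affinity A_ij = (1 + cos(z_i, z_j)) / 2.

    The affine map takes cosine similarity from [-1, 1] into [0, 1], as
    spectral clustering requires nonnegative affinities; anti-parallel
    deviation profiles are maximally dissimilar (affinity 0).
    """
    z = np.asarray(z, dtype=float)
    if z.shape[0] < 2:
        raise ValueError("need >= 2 subjects")
    norms = np.linalg.norm(z, axis=1)
    zero = np.where(norms == 0)[0]
    if zero.size:
        who = (subject_id[zero].tolist() if subject_id is not None
               else zero.tolist())
        raise ValueError(f"zero-norm deviation row(s) for subject(s) {who}")
    cos = (z / norms[:, None]) @ (z / norms[:, None]).T
    A = (1.0 + np.clip(cos, -1.0, 1.0)) / 2.0
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    return AffinityMatrix(values=A, subject_id=subject_id)


def spectral_cluster(affinity: AffinityMatrix, k: int,
                     seed: int = 0) -> ClusterSolution:
    """Ng-Jordan-Weiss spectral clustering at a fixed model order k."""
    A = affinity.values
    n = A.shape[0]
    if not (2 <= k <= n - 1):
        raise ValueError(f"k must be in [2, n-1]; got k={k}, n={n}")
    degrees = A.sum(axis=1)
    if np.any(degrees <= 0):
        logger.warning("disconnected affinity graph: jittering zero degrees")
        A = A + 1e-10
        degrees = A.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(degrees)
    L = np.eye(n) - d_inv_sqrt[:, None] * A * d_inv_sqrt[None, :]
    L = (L + L.T) / 2.0
    _, vecs = eigh(L, subset_by_index=(0, k - 1))
    row_norms = np.linalg.norm(vecs, axis=1)
    row_norms[row_norms == 0] = 1.0
    U = vecs / row_norms[:, None]
    km = KMeans(n_clusters=k, n_init=50, random_state=seed % (2 ** 31))
    raw = km.fit_predict(U)
    # Canonical labels: clusters numbered by order of first appearance.
    order = {c: i + 1 for i, c in enumerate(dict.fromkeys(raw.tolist()))}
    labels = np.array([order[c] for c in raw])
    return ClusterSolution(k=k, labels=labels, embedding=U, seed=seed)


def select_model_order(z: np.ndarray,
                       k_grid: Sequence[int] = range(2, 11),
                       cv_config: CVConfig | None = None,
                       seed: int = 0,
                       subject_id: Optional[np.ndarray] = None,
                       ) -> ModelOrderReport:
    """Choose k by cross-validated mean pairwise AUROC over a grid.

    For each candidate k the clinical cohort is clustered, a one-vs-all
    linear SVM is trained under stratified CV to discriminate the clusters
    from the deviation maps, and the mean pairwise AUROC is recorded. Ks
    where any cluster is smaller than the fold count are scored as missing.
    Ties in the argmax break toward the smaller (more parsimonious) k.
    """
    from .separability import cv_ova_decision_values, pairwise_auroc

    cv_config = cv_config or CVConfig()
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("k_grid must be nonempty")
    affinity = cosine_affinity(z, subject_id)
    seeds = derive_seeds(seed, 2 * len(k_grid))
    means: list[float] = []
    per_cluster: dict[int, list[float]] = {}
    for i, k in enumerate(k_grid):
        solution = spectral_cluster(affinity, k, seed=seeds[2 * i])
        sizes = np.bincount(solution.labels)[1:]
        if sizes.min() < cv_config.n_splits:
            logger.warning(
                "k=%d has a cluster of size %d < %d folds; scored missing",
                k, int(sizes.min()), cv_config.n_splits)
            means.append(float("nan"))
            per_cluster[k] = []
            continue
        dv = cv_ova_decision_values(z, solution.labels, cv_config,
                                    seed=seeds[2 * i + 1])
        report = pairwise_auroc(dv)
        means.append(report.grand_mean_auroc)
        per_cluster[k] = list(report.per_cluster_auroc)
    best_k, best = 0, -np.inf
    for k, score in zip(k_grid, means):
        if np.isfinite(score) and score > best:
            best_k, best = k, score
    if best_k == 0:
        raise ValueError("no feasible model order in k_grid")
    return ModelOrderReport(k_grid=k_grid, mean_pairwise_auroc=means,
                            per_cluster_auroc=per_cluster,
                            selected_k=best_k)


def _align_labels(reference: np.ndarray, other: np.ndarray,
                  k: int) -> np.ndarray:
    """Relabel ``other`` to best match ``reference`` (Hungarian on the
    contingency table); both 1-based over the same subjects."""
    contingency = np.zeros((k, k))
    for r, o in zip(reference, other):
        contingency[r - 1, o - 1] += 1
    row, col = linear_sum_assignment(-contingency)
    mapping = np.empty(k, dtype=int)
    mapping[col] = row + 1
    return mapping[other - 1]


def loo_stability(z: np.ndarray, k: int, seed: int = 0) -> dict:
    """Leave-one-out stability of the clustering at model order k.

    Each subject is removed in turn, the remaining subjects re-clustered,
    and the solution aligned to the full solution by Hungarian matching;
    reports the mean and SD of the adjusted Rand index over leave-one-out
    runs and each subject's assignment-consistency frequency.
    """
    n = z.shape[0]
    if n < k + 2:
        raise ValueError(f"need n >= k + 2 subjects; got n={n}, k={k}")
    affinity = cosine_affinity(z)
    full = spectral_cluster(affinity, k, seed=seed)
    aris: list[float] = []
    consistent = np.zeros(n)
    counted = np.zeros(n)
    n_failed = 0
    for i in range(n):
        keep = np.arange(n) != i
        sub_aff = AffinityMatrix(values=affinity.values[np.ix_(keep, keep)])
        try:
            sub = spectral_cluster(sub_aff, k, seed=seed)
        except ValueError:
            n_failed += 1
            continue
        ref = full.labels[keep]
        aris.append(adjusted_rand_score(ref, sub.labels))
        aligned = _align_labels(ref, sub.labels, k)
        consistent[keep] += (aligned == ref)
        counted[keep] += 1
    counted[counted == 0] = 1.0
    return {
        "mean_ari": float(np.mean(aris)) if aris else float("nan"),
        "sd_ari": float(np.std(aris)) if aris else float("nan"),
        "assignment_consistency": consistent / counted,
        "n_failed_runs": n_failed,
    }
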