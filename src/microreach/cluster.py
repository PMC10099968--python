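"""Activity-pattern vs receptive-field-class correspondence analysis.

Each unit's z-scored PETH is treated as a vector with one component per time
bin.  PCA reduces these vectors to their first three principal components
(which should jointly explain > 80% of the variance), k-means clusters the
projections with k equal to the number of analysable receptive-field classes,
and the match between clusters and classes is summarised by a confusion
matrix (clusters matched one-to-one to classes to maximise the diagonal) and
the Adjusted Rand Index.  The ARI is converted into a significance statistic
by recomputing it for 1000 random reassignments of the class labels
(preserving class sizes) and reporting the percentile of the observed value
within that null; a percentile above 95% is taken as significant
correspondence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import comb
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .peth import ZProfile

__all__ = [
    "ActivityMatrix",
    "PCAResult",
    "ConfusionMatrix",
    "ARIStatistic",
    "activity_matrix",
    "pca_reduce",
    "kmeans_cluster",
    "confusion_matrix",
    "adjusted_rand",
    "ari_permutation_statistic",
    "run_cluster_analysis",
]


@dataclass
class ActivityMatrix:
    """Units × time-bins matrix of z values, with per-unit class labels."""

    unit_ids: list[str]
    class_labels: np.ndarray  # rf_class per unit
    X: np.ndarray  # shape (n_units, n_bins)

    def __post_init__(self):
        self.class_labels = np.asarray(self.class_labels)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or len(self.unit_ids) != self.X.shape[0]:
            raise ValueError("X must be (n_units, n_bins) with one row per unit")
        if len(self.class_labels) != self.X.shape[0]:
            raise ValueError("one class label per unit required")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("activity matrix contains missing bins")


@dataclass
class PCAResult:
    projections: np.ndarray  # (n_units, n_components)
    explained_variance_fraction: np.ndarray
    cumulative_fraction: float


@dataclass
class ConfusionMatrix:
    """Cluster × class count table with an optimal diagonal assignment."""

    counts: np.ndarray  # (n_clusters, n_classes)
    cluster_ids: list
    class_ids: list
    cluster_to_class: dict  # cluster id -> matched class id
    diagonal_count: int


@dataclass
class ARIStatistic:
    ari_observed: float
    null_aris: np.ndarray
    percentile: float  # 100 × fraction of null strictly below observed
    n_permutations: int
    seed: int


def activity_matrix(profiles: Sequence[ZProfile]) -> ActivityMatrix:
    """Stack unit z-profiles into an analysis matrix (flagged profiles rejected)."""
    if any(zp.flagged for zp in profiles):
        raise ValueError("flagged (zero-baseline-SD) profiles cannot be clustered")
    return ActivityMatrix(
        unit_ids=[zp.unit_id or f"unit{i}" for i, zp in enumerate(profiles)],
        class_labels=np.array([zp.rf_class for zp in profiles]),
        X=np.vstack([zp.z for zp in profiles]),
    )


def pca_reduce(X: ActivityMatrix | np.ndarray, n_components: int = 3) -> PCAResult:
    """Project unit activity vectors onto the top principal components.

    Column (time-bin) mean centering only — rows are already z-scored, so no
    rescaling is applied.  Warns (does not fail) when the retained components
    explain less than 80% of the variance.
    """
    M = X.X if isinstance(X, ActivityMatrix) else np.asarray(X, dtype=float)
    n_units = M.shape[0]
    if n_units <= n_components:
        raise ValueError(f"PCA needs more than {n_components} units (got {n_units})")
    if M.shape[1] < 3:
        raise ValueError("PCA needs at least 3 time bins")
    pca = PCA(n_components=n_components, svd_solver="full")
    proj = pca.fit_transform(M)
    frac = pca.explained_variance_ratio_
    cum = float(frac.sum())
    if cum < 0.80:
        warnings.warn(
            f"first {n_components} components explain only {100 * cum:.1f}% "
            "of the variance (< 80%)",
            stacklevel=2,
        )
    return PCAResult(projections=proj, explained_variance_fraction=frac, cumulative_fraction=cum)


def kmeans_cluster(
    projections: np.ndarray,
    k: int,
    seed: int = 0,
    restarts: int = 50,
) -> np.ndarray:
    """Euclidean k-means labels, best of ``restarts`` seeded initialisations."""
    P = np.asarray(projections, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > P.shape[0]:
        raise ValueError(f"k = {k} exceeds the number of units ({P.shape[0]})")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    return km.fit_predict(P)


def _contingency(labels: np.ndarray, classes: np.ndarray):
    """Cluster × class contingency counts with sorted id lists."""
    cluster_ids, li = np.unique(labels, return_inverse=True)
    class_ids, cj = np.unique(classes, return_inverse=True)
    counts = np.zeros((len(cluster_ids), len(class_ids)), dtype=int)
    np.add.at(counts, (li, cj), 1)
    return (cluster_ids.tolist(), class_ids.tolist()), counts


def confusion_matrix(labels: Sequence, class_labels: Sequence) -> ConfusionMatrix:
    """Cluster × class counts with the diagonal-maximising one-to-one matching.

    The matching (Hungarian algorithm) pairs each cluster with at most one
    class so that the summed diagonal — units whose cluster matches their
    class — is maximal.
    """
    labels = np.asarray(labels)
    classes = np.asarray(class_labels)
    if labels.shape != classes.shape:
        raise ValueError("labels and class_labels must have equal length")
    cluster_ids, counts = _contingency(labels, classes)
    cluster_ids, class_ids = cluster_ids
    rows, cols = linear_sum_assignment(counts, maximize=True)
    assignment = {cluster_ids[r]: class_ids[c] for r, c in zip(rows, cols)}
    diag = int(counts[rows, cols].sum())
    return ConfusionMatrix(
        counts=counts,
        cluster_ids=cluster_ids,
        class_ids=class_ids,
        cluster_to_class=assignment,
        diagonal_count=diag,
    )


def adjusted_rand(labels: Sequence, class_labels: Sequence) -> float:
    """Adjusted Rand Index between two partitions of the same units.

    ARI = (Σ_ij C(n_ij,2) − E) / (M − E) with
    E = Σ_i C(a_i,2) · Σ_j C(b_j,2) / C(n,2) and
    M = ½ [Σ_i C(a_i,2) + Σ_j C(b_j,2)]; 1 for identical partitions, 0 in
    expectation under random label assignment.  Invariant to relabeling of
    either partition.
    """
    labels = np.asarray(labels)
    classes = np.asarray(class_labels)
    if labels.shape != classes.shape:
        raise ValueError("labels and class_labels must have equal length")
    n = labels.size
    if n < 2:
        raise ValueError("ARI requires at least 2 elements")
    _, cm = _contingency(labels, classes)
    sum_ij = comb(cm, 2).sum()
    a = comb(cm.sum(axis=1), 2).sum()
    b = comb(cm.sum(axis=0), 2).sum()
    expected = a * b / comb(n, 2)
    max_index = 0.5 * (a + b)
    if max_index == expected:  # both partitions trivial (all-one-cluster / all-singletons)
        return 1.0 if sum_ij == expected else 0.0
    return float((sum_ij - expected) / (max_index - expected))


def ari_permutation_statistic(
    labels: Sequence,
    class_labels: Sequence,
    n_perm: int = 1000,
    seed: int = 0,
) -> ARIStatistic:
    """Permutation percentile of the observed ARI.

    Class labels are uniformly shuffled across units (class sizes preserved)
    ``n_perm`` times; the statistic is 100 × the fraction of null ARIs
    strictly below the observed one.  Values near 100% indicate that the
    cluster–class correspondence is unlikely under random assignment.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    classes = np.asarray(class_labels)
    observed = adjusted_rand(labels, classes)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = adjusted_rand(labels, rng.permutation(classes))
    percentile = 100.0 * float(np.count_nonzero(null < observed)) / n_perm
    return ARIStatistic(
        ari_observed=observed,
        null_aris=null,
        percentile=percentile,
        n_permutations=n_perm,
        seed=seed,
    )


def run_cluster_analysis(
    profiles: Sequence[ZProfile],
    min_units_per_class: int = 4,
    purkinje_only: bool = False,
    n_components: int = 3,
    n_perm: int = 1000,
    restarts: int = 50,
    seed: int = 0,
) -> dict:
    """Full correspondence analysis on a set of classified unit profiles.

    Drops flagged or unclassified profiles (and, with ``purkinje_only``,
    everything but Purkinje simple-spike units), keeps classes with at least
    ``min_units_per_class`` units, sets k to the number of surviving classes
    and chains PCA → k-means → confusion matrix → ARI → permutation
    percentile.  Raises if fewer than two classes survive.
    """
    usable = [
        zp
        for zp in profiles
        if not zp.flagged
        and zp.rf_class is not None
        and (not purkinje_only or zp.cell_type == "purkinje_simple")
    ]
    counts: dict[int, int] = {}
    for zp in usable:
        counts[zp.rf_class] = counts.get(zp.rf_class, 0) + 1
    surviving = sorted(c for c, n in counts.items() if n >= min_units_per_class)
    if len(surviving) < 2:
        raise ValueError(
            f"cluster analysis needs >= 2 classes with >= {min_units_per_class} "
            f"units (class counts: {counts})"
        )
    selected = [zp for zp in usable if zp.rf_class in surviving]
    am = activity_matrix(selected)
    k = len(surviving)
    pca = pca_reduce(am, n_components=n_components)
    labels = kmeans_cluster(pca.projections, k=k, seed=seed, restarts=restarts)
    cm = confusion_matrix(labels, am.class_labels)
    stat = ari_permutation_statistic(labels, am.class_labels, n_perm=n_perm, seed=seed)
    return {
        "n_units": len(selected),
        "k": k,
        "classes": surviving,
        "class_counts": {int(c): int(counts[c]) for c in surviving},
        "purkinje_only": purkinje_only,
        "explained_variance": [float(v) for v in pca.explained_variance_fraction],
        "cumulative_variance": pca.cumulative_fraction,
        "cluster_labels": labels.tolist(),
        "unit_ids": am.unit_ids,
        "confusion_counts": cm.counts.tolist(),
        "cluster_ids": [int(c) for c in cm.cluster_ids],
        "class_ids": [int(c) for c in cm.class_ids],
        "assignment": {int(a): int(b) for a, b in cm.cluster_to_class.items()},
        "diagonal_count": cm.diagonal_count,
        "ari": stat.ari_observed,
        "percentile": stat.percentile,
        "n_perm": n_perm,
        "seed": seed,
        "restarts": restarts,
    }
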