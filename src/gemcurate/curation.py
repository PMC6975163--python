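"""Curation-target analysis: cluster essentiality profiles, classify the
clusters from reaction content, and score each variable reaction.

The pipeline: (1) collapse perfectly correlated gene columns of the
member × gene essentiality matrix (without this, duplicated columns skew
k-means toward one dominant cluster); (2) k-means with k = 2 on the
collapsed binary profiles; (3) a random forest predicts each member's
cluster from its variable-reaction presence vector; (4) each reaction is
scored by *fractional importance* (normalized Gini importance, summing to
1 across reactions) and *cluster ratio* 1 − min(f₁,f₂)/max(f₁,f₂), where
f_c is the reaction's presence frequency within cluster c — 1 when the
reaction is exclusive to one cluster, 0 when evenly distributed.
Reactions scoring high on both metrics are the top curation targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier

from .ensemble import Ensemble, EssentialityMatrix
from .errors import ValidationError

KMEANS_MAX_ITER = 300
KMEANS_TOL = 1e-4
RF_N_TREES = 500


# ---------------------------------------------------------------------------
# Collapsing correlated genes
# ---------------------------------------------------------------------------

def collapse_correlated_genes(
    matrix: EssentialityMatrix,
) -> tuple[np.ndarray, list[str], list[list[str]]]:
    """Drop constant gene columns and merge exactly identical ones.

    Returns ``(reduced, representatives, groups)``: a member × k boolean
    array, the representative gene id per column, and the full gene group
    behind each column.  "Perfectly correlated" means exact column
    equality.  Raises when no gene prediction varies across members.
    """
    values = matrix.values
    if values.size == 0:
        raise ValidationError("empty essentiality matrix")
    variable = values.any(axis=0) & (~values).any(axis=0)
    if not variable.any():
        raise ValidationError("no variable essentiality predictions")
    groups_by_key: dict[bytes, list[int]] = {}
    for j in np.flatnonzero(variable):
        groups_by_key.setdefault(values[:, j].tobytes(), []).append(j)
    cols = sorted(groups_by_key.values(), key=lambda g: g[0])
    reduced = np.column_stack([values[:, g[0]] for g in cols])
    reps = [matrix.genes[g[0]] for g in cols]
    groups = [[matrix.genes[j] for j in g] for g in cols]
    return reduced, reps, groups


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    k: int
    inertia: float
    collapsed_groups: list[list[str]]

    def label_array(self, member_ids: list[str]) -> np.ndarray:
        return np.array([self.labels[m] for m in member_ids])


def cluster_members(
    reduced: np.ndarray,
    member_ids: list[str],
    k: int = 2,
    seed: int = 0,
    collapsed_groups: list[list[str]] | None = None,
) -> ClusterAssignment:
    """k-means (k = 2) on collapsed binary essentiality profiles.

    Elkan's accelerated algorithm, 300 max iterations, tolerance 1e-4,
    k-means++ initialization with 10 restarts.  Labels are arbitrary up to
    permutation.
    """
    X = np.asarray(reduced, dtype=float)
    if len({tuple(r) for r in X}) < k:
        raise ValidationError(f"fewer than k={k} distinct member profiles")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=10,
        max_iter=KMEANS_MAX_ITER,
        tol=KMEANS_TOL,
        algorithm="elkan",
        random_state=seed,
    ).fit(X)
    labels = {m: int(l) for m, l in zip(member_ids, km.labels_)}
    if len(set(labels.values())) != k:
        raise ValidationError(f"k-means produced fewer than k={k} clusters")
    return ClusterAssignment(labels, k, float(km.inertia_), collapsed_groups or [])


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    coordinates: np.ndarray  # members × axes
    explained_fraction: np.ndarray
    member_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates,
            index=pd.Index(self.member_ids, name="member"),
            columns=[f"PC{i + 1}" for i in range(self.coordinates.shape[1])],
        )


def pcoa_hamming(matrix: EssentialityMatrix) -> PcoaResult:
    """Principal coordinate analysis of pairwise Hamming distances.

    Distance = fraction of gene calls differing between two members.
    Coordinates are scaled by √eigenvalue; negative eigenvalues (possible
    with non-Euclidean distances, a safety net here) are truncated to zero
    and excluded from the explained-fraction normalization.
    """
    values = matrix.values.astype(float)
    n = values.shape[0]
    if n < 2:
        raise ValidationError("PCoA requires at least 2 members")
    dist = squareform(pdist(values, metric="hamming"))
    if not dist.any():
        return PcoaResult(
            np.zeros((n, 1)), np.zeros(1), list(matrix.member_ids)
        )
    import warnings

    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    with warnings.catch_warnings():
        # negative eigenvalues are truncated below; skbio's warning is noise
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(DistanceMatrix(dist, ids=matrix.member_ids))
    eig = res.eigvals.to_numpy()
    coords = res.samples.to_numpy()
    coords[:, eig < 0] = 0.0
    pos = np.clip(eig, 0.0, None)
    explained = pos / pos.sum() if pos.sum() > 0 else np.zeros_like(pos)
    return PcoaResult(coords, explained, list(matrix.member_ids))


# ---------------------------------------------------------------------------
# Classification and metrics
# ---------------------------------------------------------------------------

def train_cluster_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
) -> tuple[RandomForestClassifier, float]:
    """Random forest predicting cluster membership from reaction presence.

    500 trees, Gini criterion, no depth limit, min 2 samples per split,
    min 1 per leaf, √(n features) candidates per split, bootstrap
    resampling; out-of-bag accuracy reported.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValidationError("at least one variable reaction feature is required")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("labels contain a single class")
    if counts.min() < 2:
        raise ValidationError("each cluster needs at least 2 members")
    clf = RandomForestClassifier(
        n_estimators=RF_N_TREES,
        criterion="gini",
        max_depth=None,
        min_samples_split=2,
        min_samples_leaf=1,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
    ).fit(X, y)
    return clf, float(clf.oob_score_)


def holdout_accuracy(
    features: np.ndarray, labels: np.ndarray, seed: int = 0, test_fraction: float = 0.3
) -> float:
    """70/30 split cross-check of the OOB accuracy estimate."""
    from sklearn.model_selection import train_test_split

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, random_state=seed, stratify=y
    )
    clf = RandomForestClassifier(
        n_estimators=RF_N_TREES,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
    ).fit(X_tr, y_tr)
    return float(clf.score(X_te, y_te))


def fractional_importance(
    classifier: RandomForestClassifier, reaction_ids: list[str]
) -> dict[str, float]:
    """Gini mean-decrease-in-impurity importances normalized to sum 1."""
    imp = np.asarray(classifier.feature_importances_, dtype=float)
    total = imp.sum()
    if total <= 0:
        # no split ever used a feature; spread uniformly so the sum-to-1
        # contract holds
        imp = np.full_like(imp, 1.0 / len(imp))
    else:
        imp = imp / total
    return dict(zip(reaction_ids, imp.tolist()))


def cluster_ratio(
    feature_matrix: np.ndarray,
    labels: np.ndarray,
    reaction_ids: list[str],
) -> dict[str, tuple[float, float, float]]:
    """Per-reaction (ratio, f1, f2) with f_c the within-cluster presence
    frequency and ratio = 1 − min(f1,f2)/max(f1,f2).

    Symmetric under label swap.  Reactions absent from every member of
    both clusters are excluded (not variable).
    """
    X = np.asarray(feature_matrix, dtype=bool)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValidationError(f"expected exactly 2 clusters, got {len(classes)}")
    mask1 = y == classes[0]
    mask2 = y == classes[1]
    if not mask1.any() or not mask2.any():
        raise ValidationError("empty cluster")
    f1 = X[mask1].mean(axis=0)
    f2 = X[mask2].mean(axis=0)
    out: dict[str, tuple[float, float, float]] = {}
    for rid, a, b in zip(reaction_ids, f1, f2):
        lo, hi = (a, b) if a <= b else (b, a)
        if hi == 0:
            continue
        out[rid] = (float(1.0 - lo / hi), float(a), float(b))
    return out


@dataclass
class CurationMetrics:
    """Per-reaction curation scores plus classifier-level OOB accuracy."""

    table: pd.DataFrame  # index reaction_id; fractional_importance, cluster_ratio, f1, f2
    oob_accuracy: float

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def compute_curation_metrics(
    ensemble: Ensemble,
    assignment: ClusterAssignment,
    seed: int = 0,
) -> CurationMetrics:
    """Train the cluster classifier and assemble both curation metrics."""
    labels = assignment.label_array(ensemble.member_ids)
    clf, oob = train_cluster_classifier(ensemble.feature_matrix, labels, seed=seed)
    imp = fractional_importance(clf, ensemble.variable_reactions)
    ratios = cluster_ratio(
        ensemble.feature_matrix, labels, ensemble.variable_reactions
    )
    rows = []
    for rid in ensemble.variable_reactions:
        ratio, f1, f2 = ratios.get(rid, (np.nan, np.nan, np.nan))
        rows.append((rid, imp[rid], ratio, f1, f2))
    table = pd.DataFrame(
        rows,
        columns=["reaction_id", "fractional_importance", "cluster_ratio", "f1", "f2"],
    ).set_index("reaction_id")
    return CurationMetrics(table, oob)


def curation_targets(metrics: CurationMetrics, top: int | None = None) -> pd.DataFrame:
    """Reactions ranked by fractional importance (desc); ties broken by
    cluster ratio (desc) then reaction id (asc)."""
    df = metrics.table.reset_index()
    df = df.sort_values(
        by=["fractional_importance", "cluster_ratio", "reaction_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if top is not None:
        df = df.head(top)
    return df
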