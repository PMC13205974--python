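"""Trajectory phenotyping: PCA subspace, K-means, validity, gamma ordering.

The S x 50 lateral-translation feature matrix is projected onto the leading
principal components retaining at least 95% of variance (features share mm
units, so PCA uses centering without per-feature scaling).  K-means with
k-means++ seeding and multiple restarts clusters the latent points; the
cluster count is chosen by joint evaluation of the inertia elbow (maximum
second difference) and the silhouette coefficient among the elbow's
neighbours.  Finally clusters are relabelled by the order parameter gamma —
the within-cluster mean of each subject's maximum lateral displacement — so
that Type 1 is always the most laterally displaced phenotype and type indices
read as a clinical severity gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .exceptions import InvalidArgumentError
from .standardize import KinematicSummary


@dataclass
class LatentEmbedding:
    """PCA projection retaining >= the requested cumulative variance."""

    projection: np.ndarray  # (S, d)
    basis: np.ndarray  # (50, d), orthonormal columns
    mean: np.ndarray  # feature-space mean
    eigenvalues: np.ndarray  # retained covariance eigenvalues
    full_spectrum: np.ndarray  # all eigenvalues, for variance accounting
    d: int

    @property
    def cumulative_variance_ratio(self) -> float:
        return float(self.eigenvalues.sum() / self.full_spectrum.sum())


@dataclass
class ValidityIndices:
    silhouette: float
    davies_bouldin: float
    calinski_harabasz: float
    notes: str | None = None


@dataclass
class ClusterModel:
    """K-means partition with optional gamma ordering and validity indices."""

    K: int
    labels: np.ndarray  # per-subject type index in 1..K
    centroids: np.ndarray  # (K, d) in latent space, row j for type j+1
    inertia: float
    gamma: np.ndarray | None = None  # per-type mean max lateral displacement (mm)
    validity: ValidityIndices | None = None
    subject_ids: list = field(default_factory=list)


def _as_matrix(X) -> np.ndarray:
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise InvalidArgumentError("feature matrix must be 2-D")
    return arr


def pca_project(X, variance_threshold: float = 0.95) -> LatentEmbedding:
    """Project features onto the smallest subspace retaining the threshold.

    ``d`` is the smallest dimension whose cumulative explained-variance ratio
    reaches ``variance_threshold``; the basis columns are the leading
    eigenvectors of the centered covariance.
    """
    arr = _as_matrix(X)
    if arr.shape[0] < 2:
        raise InvalidArgumentError("PCA needs at least 2 rows")
    if not 0.0 < variance_threshold <= 1.0:
        raise InvalidArgumentError("variance_threshold must lie in (0, 1]")
    pca = PCA(n_components=min(arr.shape[0] - 1, arr.shape[1]), svd_solver="full")
    scores = pca.fit_transform(arr)
    spectrum = pca.explained_variance_
    if spectrum.sum() <= 0 or not np.isfinite(spectrum.sum()):
        raise InvalidArgumentError("feature matrix has zero variance")
    cum = np.cumsum(pca.explained_variance_ratio_)
    d = int(np.argmax(cum >= variance_threshold - 1e-12)) + 1
    return LatentEmbedding(
        projection=scores[:, :d],
        basis=pca.components_[:d].T,
        mean=pca.mean_,
        eigenvalues=spectrum[:d],
        full_spectrum=spectrum,
        d=d,
    )


def kmeans_fit(Z, K: int, seed: int, restarts: int = 50,
               subject_ids: list | None = None) -> ClusterModel:
    """Best-of-restarts Lloyd's algorithm with k-means++ seeding.

    Labels are reported as 1..K (unordered); ``inertia`` is the minimum
    within-cluster sum of squares across restarts.
    """
    arr = _as_matrix(Z)
    S = arr.shape[0]
    if K < 2 or K > S:
        raise InvalidArgumentError(f"K={K} must satisfy 2 <= K <= {S}")
    km = KMeans(n_clusters=K, n_init=restarts, random_state=int(seed) % (2**32),
                init="k-means++")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign duplicate-point warnings at K ~ S
        km.fit(arr)
    return ClusterModel(
        K=K,
        labels=km.labels_.astype(int) + 1,
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        subject_ids=list(subject_ids) if subject_ids is not None else [],
    )


def validity_indices(Z, labels: np.ndarray) -> ValidityIndices:
    """Silhouette, Davies-Bouldin and Calinski-Harabasz (Euclidean)."""
    arr = _as_matrix(Z)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise InvalidArgumentError("validity indices need at least 2 clusters")
    if np.all(counts == 1):
        return ValidityIndices(
            float("nan"), float("nan"), float("nan"),
            notes="all clusters are singletons; indices undefined",
        )
    return ValidityIndices(
        silhouette=float(silhouette_score(arr, labels)),
        davies_bouldin=float(davies_bouldin_score(arr, labels)),
        calinski_harabasz=float(calinski_harabasz_score(arr, labels)),
    )


#: An inertia-curve inflection is "clear" when its second difference exceeds
#: every other candidate's by this factor; only ambiguous elbows are
#: arbitrated by silhouette.
ELBOW_DOMINANCE = 2.0


def select_k(Z, k_range: tuple[int, int] = (2, 6), seed: int = 0,
             restarts: int = 50) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count by joint elbow/silhouette evaluation.

    The elbow candidate maximizes the second difference of inertia over the
    K grid.  When that inflection clearly dominates (its curvature is at
    least ``ELBOW_DOMINANCE`` times the runner-up's), the elbow K is chosen
    outright — the silhouette of a small extreme cluster against a broad
    continuum otherwise always votes for K=2 regardless of finer structure.
    When the inflection is ambiguous (including grids whose true elbow lies
    at the boundary, where the second difference cannot see it) the
    silhouette arbitrates over the whole grid.  Returns (K, diagnostics).
    """
    arr = _as_matrix(Z)
    S = arr.shape[0]
    lo, hi = k_range
    if not (2 <= lo <= hi <= S - 1):
        raise InvalidArgumentError(f"k_range must lie within [2, {S - 1}]")
    if np.allclose(arr, arr[0]):
        raise InvalidArgumentError("all latent points identical; clustering degenerate")
    ks = list(range(lo, hi + 1))
    inertias, silhouettes = [], []
    for k in ks:
        model = kmeans_fit(arr, k, seed=seed, restarts=restarts)
        inertias.append(model.inertia)
        try:
            sil = float(silhouette_score(arr, model.labels))
        except ValueError:
            sil = float("nan")
        silhouettes.append(sil)
    diag = pd.DataFrame({"K": ks, "inertia": inertias, "silhouette": silhouettes})
    if len(ks) >= 3:
        second_diff = np.array(
            [inertias[i - 1] - 2 * inertias[i] + inertias[i + 1] for i in range(1, len(ks) - 1)]
        )
        best = int(np.argmax(second_diff))
        elbow = ks[1 + best]
        runner_up = max(
            (second_diff[i] for i in range(len(second_diff)) if i != best), default=0.0
        )
        dominant = second_diff[best] > 0 and (
            runner_up <= 0 or second_diff[best] >= ELBOW_DOMINANCE * runner_up
        )
        if dominant:
            return elbow, diag
    chosen = ks[int(np.nanargmax(silhouettes))]
    return chosen, diag


def order_by_gamma(model: ClusterModel, summaries: list[KinematicSummary]) -> ClusterModel:
    """Relabel clusters by descending gamma (mean max lateral displacement).

    After relabelling, Type 1 is the most laterally displaced phenotype and
    gamma is strictly decreasing in the type index; validity indices are
    unchanged because the partition itself is untouched.
    """
    if len(summaries) != len(model.labels):
        raise InvalidArgumentError("one kinematic summary per subject required")
    max_disp = np.array([s.max_lateral_displacement for s in summaries])
    gammas = np.array(
        [max_disp[model.labels == j].mean() for j in range(1, model.K + 1)]
    )
    order = np.argsort(-gammas, kind="stable")  # old type index - 1, descending gamma
    if model.K > 1:
        sorted_g = gammas[order]
        if np.any(np.abs(np.diff(sorted_g)) <= 1e-9):
            warnings.warn("gamma ties between clusters; stable order by original label")
    relabel = np.empty(model.K, dtype=int)
    for new_type, old_idx in enumerate(order, start=1):
        relabel[old_idx] = new_type
    return ClusterModel(
        K=model.K,
        labels=relabel[model.labels - 1],
        centroids=model.centroids[order],
        inertia=model.inertia,
        gamma=gammas[order],
        validity=model.validity,
        subject_ids=model.subject_ids,
    )
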