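"""Typing extracted synergies by their movement-activation profiles.

Electrode weight vectors cannot be compared across subjects when
electrode placement is not anatomically precise, so each synergy is
instead summarized by how strongly it activates across the 17 simple
hand/wrist movements: element ``m`` of the profile is the mean
activation coefficient over all samples of movement ``m``, and the
profile is z-scored across movements to remove the scale ambiguity of
the factorization.

Profiles pooled over control subjects are clustered with k-means under
the correlation distance ``1 - r`` (Pearson). The cluster count is the
one (scanned over 2..15, 50 restarts each) that maximizes the mean
silhouette score. Each cluster centroid is read out as representative
movements: the strongest movement if it exceeds the centroid mean by
2 S.D. (primary) and the second strongest if it exceeds the mean by
1 S.D. (secondary).

Patient synergies are never pooled into the control clustering; they are
assigned post hoc to the nearest centroid, provided that distance does
not exceed the cluster's maximum within-cluster sample-to-centroid
distance — otherwise the synergy is reported as untyped (cluster 0).
Cluster ids are therefore 1-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError
from .nmf import SynergyModel, vaf_global

#: Movement ids of the 17 single/multi-joint hand and wrist movements
#: (thumb up ... wrist extension with closed hand) used for profiles.
EXERCISE_B_MOVEMENTS: tuple[int, ...] = tuple(range(1, 18))


@dataclass
class SynergyFeature:
    """Z-scored movement-activation profile of one extracted synergy."""

    profile: np.ndarray
    subject_id: str
    synergy_index: int
    explained_variance_share: float | None = None

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=float)
        if abs(self.profile.mean()) > 1e-9 or abs(self.profile.std() - 1.0) > 1e-9:
            raise ValueError("profile must be z-scored (mean 0, population SD 1)")


@dataclass
class ClusterModel:
    """K-means partition of synergy profiles under correlation distance."""

    n_clusters: int
    assignment: np.ndarray          # 1-based cluster id per feature
    centroids: np.ndarray           # (n_clusters, n_movements), z-scored rows
    silhouette_by_k: dict[int, float]
    max_within_distance: np.ndarray  # per cluster
    representatives: list[tuple[int | None, int | None]]
    movement_ids: tuple[int, ...] = EXERCISE_B_MOVEMENTS


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd <= 1e-12:
        raise DegenerateDataError("constant vector cannot be z-scored")
    return (x - x.mean()) / sd


def corr_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Correlation distance ``1 - r`` (Pearson); ranges over [0, 2]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be 1-D vectors of equal length")
    su, sv = u.std(), v.std()
    if su <= 1e-12 or sv <= 1e-12:
        raise DegenerateDataError("correlation undefined for constant vectors")
    r = float(np.mean((u - u.mean()) * (v - v.mean())) / (su * sv))
    return 1.0 - r


def per_synergy_variance(E: np.ndarray, W: np.ndarray, H: np.ndarray,
                         i: int) -> float:
    """Percent of EMG variance explained by synergy ``i`` alone: the
    global VAF of the rank-1 reconstruction ``W[:, i] @ H[i, :]``."""
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if not 0 <= i < W.shape[1]:
        raise IndexError(f"synergy index {i} out of range [0, {W.shape[1]})")
    R = np.outer(W[:, i], H[i, :])
    return vaf_global(E, R)


def build_features(model: SynergyModel, movement_of_sample: np.ndarray,
                   movement_list: tuple[int, ...] = EXERCISE_B_MOVEMENTS,
                   E: np.ndarray | None = None) -> list[SynergyFeature]:
    """One movement-activation profile per synergy of a fitted model.

    Parameters
    ----------
    E
        The pooled envelope the model was fitted on; when given, each
        feature also carries its per-synergy explained-variance share.

    Raises
    ------
    DegenerateDataError
        If a listed movement has no samples, or a synergy's raw profile
        is constant across movements (untypable synergy).
    """
    movement_of_sample = np.asarray(movement_of_sample, dtype=int)
    if model.H.shape[1] != len(movement_of_sample):
        raise ValueError("H and movement_of_sample are misaligned")
    masks = []
    for m in movement_list:
        mask = movement_of_sample == m
        if not mask.any():
            raise DegenerateDataError(f"movement {m} has no samples")
        masks.append(mask)
    features = []
    for i in range(model.k):
        raw = np.array([model.H[i, mask].mean() for mask in masks])
        if raw.std() <= 1e-12:
            raise DegenerateDataError(
                f"synergy {i} has a constant activation profile "
                "across movements (untypable)"
            )
        share = None
        if E is not None:
            share = per_synergy_variance(E, model.W, model.H, i)
        features.append(SynergyFeature(
            profile=_zscore(raw),
            subject_id="",
            synergy_index=i,
            explained_variance_share=share,
        ))
    return features


# ---------------------------------------------------------------------------
# k-means under correlation distance

def _profiles_matrix(features) -> np.ndarray:
    if len(features) and isinstance(features[0], SynergyFeature):
        X = np.vstack([f.profile for f in features])
    else:
        X = np.asarray(features, dtype=float)
    return X


def _corr_dist_matrix(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Pairwise 1 - r between rows of X and rows of C (both z-scored)."""
    M = X.shape[1]
    return 1.0 - (X @ C.T) / M


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, float]:
    """One k-means run; returns (labels, centroids, total within distance).

    Rows of X must be z-scored, so ``r = x . c / M`` and the centroid of a
    member set is the re-z-scored arithmetic mean, which makes the Lloyd
    iteration monotone under 1 - r. An emptied cluster is reseeded from
    the sample farthest from its current centroid.
    """
    N = X.shape[0]
    C = X[rng.choice(N, size=k, replace=False)].copy()
    labels = np.full(N, -1)
    for _ in range(max_iter):
        D = _corr_dist_matrix(X, C)
        new_labels = D.argmin(axis=1)
        if (new_labels == labels).all():
            break
        labels = new_labels
        for j in range(k):
            members = X[labels == j]
            if len(members) == 0:
                far = D[np.arange(N), labels].argmax()
                C[j] = X[far]
                labels[far] = j
            else:
                mean = members.mean(axis=0)
                sd = mean.std()
                if sd <= 1e-12:
                    # members cancel out exactly; fall back to one member
                    C[j] = members[0]
                else:
                    C[j] = (mean - mean.mean()) / sd
    D = _corr_dist_matrix(X, C)
    inertia = float(D[np.arange(N), labels].sum())
    return labels, C, inertia


def mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette score from a precomputed distance matrix.

    Singleton clusters contribute a silhouette of 0.
    """
    N = D.shape[0]
    uniq = np.unique(labels)
    s = np.zeros(N)
    for i in range(N):
        own = labels[i]
        same = (labels == own)
        n_own = same.sum()
        if n_own <= 1:
            s[i] = 0.0
            continue
        a = D[i, same].sum() / (n_own - 1)
        b = min(D[i, labels == other].mean() for other in uniq if other != own)
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


def cluster_features(features, k_range=range(2, 16), restarts: int = 50,
                     seed: int = 0,
                     movement_ids: tuple[int, ...] = EXERCISE_B_MOVEMENTS,
                     ) -> ClusterModel:
    """Cluster z-scored synergy profiles and pick the cluster count by
    mean silhouette.

    For each candidate ``k`` the best of ``restarts`` Lloyd runs (by total
    within-cluster distance) is kept; the returned model is the one whose
    partition maximizes the mean silhouette under correlation distance.
    Ties prefer the smaller ``k``.
    """
    X = _profiles_matrix(features)
    N = X.shape[0]
    ks = list(k_range)
    if not ks:
        raise ValueError("empty k_range")
    if N < max(ks) + 1:
        raise ValueError(
            f"need at least max(k_range)+1 = {max(ks) + 1} features, got {N}"
        )
    Dfull = _corr_dist_matrix(X, X)
    np.fill_diagonal(Dfull, 0.0)
    silhouette_by_k: dict[int, float] = {}
    best = None  # (silhouette, k, labels, centroids)
    for k in ks:
        ss = np.random.SeedSequence(seed, spawn_key=(k,))
        best_run = None  # (inertia, labels, centroids)
        for r, child in enumerate(ss.spawn(restarts)):
            rng = np.random.default_rng(child)
            labels, C, inertia = _lloyd(X, k, rng)
            if best_run is None or inertia < best_run[0]:
                best_run = (inertia, labels, C)
        sil = mean_silhouette(Dfull, best_run[1])
        silhouette_by_k[k] = sil
        if best is None or sil > best[0]:
            best = (sil, k, best_run[1], best_run[2])
    _, k_opt, labels, C = best
    # relabel clusters by decreasing size for stable reporting; ties by
    # first occurrence
    sizes = np.array([(labels == j).sum() for j in range(k_opt)])
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k_opt, dtype=int)
    remap[order] = np.arange(k_opt)
    labels = remap[labels]
    C = C[order]
    D = _corr_dist_matrix(X, C)
    max_within = np.array([
        D[labels == j, j].max() for j in range(k_opt)
    ])
    reps = [representative_movements(C[j], movement_ids) for j in range(k_opt)]
    return ClusterModel(
        n_clusters=k_opt,
        assignment=labels + 1,
        centroids=C,
        silhouette_by_k=silhouette_by_k,
        max_within_distance=max_within,
        representatives=reps,
        movement_ids=tuple(movement_ids),
    )


def representative_movements(centroid: np.ndarray,
                             movement_ids: tuple[int, ...] = EXERCISE_B_MOVEMENTS,
                             ) -> tuple[int | None, int | None]:
    """Primary/secondary representative movements of a cluster centroid.

    With ``m`` and ``s`` the mean and population S.D. across the
    centroid's movement entries: the primary representative is the
    strongest movement if its activation is at least ``m + 2s``; the
    secondary is the second-strongest movement if its activation is at
    least ``m + 1s``. Ties are broken toward the lower movement id. A
    constant centroid has no representatives.
    """
    c = np.asarray(centroid, dtype=float)
    if len(c) != len(movement_ids):
        raise ValueError("centroid length does not match movement list")
    m, s = c.mean(), c.std()
    if s <= 1e-12:
        return (None, None)
    # sort by decreasing activation, ties toward lower index
    order = np.lexsort((np.arange(len(c)), -c))
    first, second = order[0], order[1]
    primary = movement_ids[first] if c[first] >= m + 2 * s else None
    secondary = movement_ids[second] if c[second] >= m + 1 * s else None
    return (primary, secondary)


def assign_patient_synergy(feature, clusters: ClusterModel) -> int:
    """Type a patient synergy against control clusters.

    Returns the 1-based id of the nearest centroid if its correlation
    distance does not exceed that cluster's maximum within-cluster
    sample-to-centroid distance, else 0 (untyped). Any feature that took
    part in the clustering is therefore always assigned to its own
    cluster.
    """
    profile = feature.profile if isinstance(feature, SynergyFeature) else \
        np.asarray(feature, dtype=float)
    d = np.array([corr_distance(profile, c) for c in clusters.centroids])
    j = int(d.argmin())
    if d[j] <= clusters.max_within_distance[j] + 1e-12:
        return j + 1
    return 0
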