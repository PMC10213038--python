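"""Soft clustering of session feature vectors into digital EEG phenotypes.

Two algorithms are supported on the 135-dimensional relative band-power
feature space:

* **Fuzzy C-Means** (FCM), implemented here. Alternating updates of
  memberships ``u_ij`` proportional to ``(1/d_ij)^(2/(m-1))`` (normalized per
  sample) and centers ``v_j = sum_i u_ij^m x_i / sum_i u_ij^m`` minimize the
  objective ``J = sum_ij u_ij^m d_ij^2``. The fuzzification exponent ``m``
  (default 1.7) controls membership softness; ``m -> 1`` recovers k-means,
  large ``m`` drives memberships toward uniform.
* **Spectral clustering** (scikit-learn, RBF affinity on the normalized
  graph Laplacian) producing hard labels; cluster prototypes are then the
  per-cluster means and soft memberships are derived from the normalized
  inverse Euclidean distance of each sample to the prototypes.

Session-level memberships are averaged over each subject's sessions to give
one membership profile per subject; the hard phenotype is the argmax.
Clusters are numbered 1..k in all public outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import SpectralClustering, kmeans_plusplus
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)
from sklearn.metrics.pairwise import euclidean_distances, rbf_kernel


@dataclass
class ClusterModel:
    algorithm: str                  # 'fcm' | 'spectral'
    k: int
    params: dict
    prototypes: np.ndarray          # (k, d)
    memberships: np.ndarray         # (N, k), row-stochastic
    fit_seed: int
    n_iter: int = 0
    objective_trace: np.ndarray | None = None

    @property
    def hard_labels(self) -> np.ndarray:
        """1-based hard assignments (ties -> lowest cluster index)."""
        return self.memberships.argmax(axis=1) + 1


@dataclass
class SubjectMembership:
    subject_id: str
    membership: np.ndarray  # length k, sums to 1
    hard_cluster: int       # 1-based


# ---------------------------------------------------------------------------
# Fuzzy C-Means
# ---------------------------------------------------------------------------

def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances; a sample coincident with a
    center receives membership 1 there (standard singularity rule)."""
    u = np.zeros_like(d2)
    zero = d2 <= 1e-300
    singular = zero.any(axis=1)
    if singular.any():
        rows = np.where(singular)[0]
        u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    regular = ~singular
    if regular.any():
        inv = d2[regular] ** (-1.0 / (m - 1.0))
        u[regular] = inv / inv.sum(axis=1, keepdims=True)
    return u


def fcm_fit(X: np.ndarray, k: int, m: float = 1.7, tol: float = 1e-6,
            max_iter: int = 300, seed: int = 0, n_init: int = 5) -> ClusterModel:
    """Fit Fuzzy C-Means by alternating membership/center updates until the
    maximum center displacement falls below ``tol``.

    Centers are seeded with k-means++ sampling; ``n_init`` restarts are run
    and the solution with the lowest final objective is kept (the FCM
    objective is non-convex and a single start can stall in a local
    minimum)."""
    X = np.asarray(X, float)
    n = X.shape[0]
    if m <= 1:
        raise ValueError("fuzzification m must be > 1")
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need at least k samples")
    best: ClusterModel | None = None
    for restart in range(n_init):
        centers, _ = kmeans_plusplus(X, k, random_state=seed + restart)
        trace = []
        for it in range(1, max_iter + 1):
            d2 = euclidean_distances(X, centers, squared=True)
            u = _fcm_memberships(d2, m)
            trace.append(float((u**m * d2).sum()))
            um = u**m
            new_centers = (um.T @ X) / um.sum(axis=0)[:, None]
            shift = np.abs(new_centers - centers).max()
            centers = new_centers
            if shift < tol:
                break
        d2 = euclidean_distances(X, centers, squared=True)
        u = _fcm_memberships(d2, m)
        model = ClusterModel("fcm", k, {"m": m, "tol": tol}, centers, u, seed,
                             n_iter=it, objective_trace=np.asarray(trace))
        if best is None or trace[-1] < best.objective_trace[-1]:
            best = model
    return best


# ---------------------------------------------------------------------------
# Spectral clustering
# ---------------------------------------------------------------------------

def spectral_fit(X: np.ndarray, k: int, n_components: int | None = None,
                 seed: int = 0, gamma: float | None = None,
                 eps: float = 1e-12) -> np.ndarray:
    """Hard labels (1..k) from normalized-Laplacian spectral clustering.

    RBF affinity with gamma = 1/d by default; a small uniform affinity
    floor ``eps`` keeps the graph connected. The embedding is clustered by
    k-means with 10 seeded restarts."""
    X = np.asarray(X, float)
    if X.shape[0] < k:
        raise ValueError("need at least k samples")
    if gamma is None:
        gamma = 1.0 / X.shape[1]
    affinity = rbf_kernel(X, gamma=gamma) + eps
    sc = SpectralClustering(
        n_clusters=k, n_components=n_components or k, affinity="precomputed",
        assign_labels="kmeans", n_init=10, random_state=seed,
    )
    return sc.fit_predict(affinity) + 1


def prototypes_from_labels(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-cluster mean feature vectors; labels are 1..k."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    k = int(labels.max())
    protos = np.empty((k, X.shape[1]))
    for c in range(1, k + 1):
        mask = labels == c
        if not mask.any():
            raise ValueError(f"cluster {c} is empty")
        protos[c - 1] = X[mask].mean(axis=0)
    return protos


def soft_membership_from_distance(X: np.ndarray, prototypes: np.ndarray,
                                  kind: str = "inverse",
                                  tau: float = 1.0) -> np.ndarray:
    """Row-stochastic memberships from Euclidean distances to prototypes.

    ``inverse`` (default): u_ic = (1/d_ic) / sum_c' (1/d_ic'); a sample on a
    prototype gets membership 1 there. ``softmax``: u ~ exp(-d^2 / tau)."""
    d = euclidean_distances(np.asarray(X, float), np.asarray(prototypes, float))
    if kind == "softmax":
        logits = -(d**2) / tau
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)
    if kind != "inverse":
        raise ValueError("kind must be 'inverse' or 'softmax'")
    u = np.zeros_like(d)
    zero = d <= 1e-300
    singular = zero.any(axis=1)
    if singular.any():
        rows = np.where(singular)[0]
        u[rows] = zero[rows] / zero[rows].sum(axis=1, keepdims=True)
    regular = ~singular
    if regular.any():
        inv = 1.0 / d[regular]
        u[regular] = inv / inv.sum(axis=1, keepdims=True)
    return u


def spectral_model(X: np.ndarray, k: int, n_components: int | None = None,
                   seed: int = 0, **kwargs) -> ClusterModel:
    """Spectral clustering wrapped as a ClusterModel with prototype-derived
    soft memberships."""
    labels = spectral_fit(X, k, n_components, seed, **kwargs)
    protos = prototypes_from_labels(X, labels)
    u = soft_membership_from_distance(X, protos)
    return ClusterModel("spectral", k, {"n_components": n_components or k},
                        protos, u, seed)


def fit_model(X: np.ndarray, algorithm: str, k: int, seed: int = 0,
              m: float = 1.7, n_components: int | None = None) -> ClusterModel:
    if algorithm == "fcm":
        return fcm_fit(X, k, m=m, seed=seed)
    if algorithm == "spectral":
        return spectral_model(X, k, n_components=n_components, seed=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# Subject-level membership
# ---------------------------------------------------------------------------

def hard_assign(membership: np.ndarray) -> int:
    """1-based argmax over membership values; e.g. (0.2, 0.3, 0.4, 0.1)
    belongs to cluster 3. Ties break toward the lowest index."""
    membership = np.asarray(membership, float)
    if membership.size == 0:
        raise ValueError("empty membership vector")
    return int(membership.argmax()) + 1


def average_subject_membership(memberships: np.ndarray,
                               subject_ids: list[str]) -> list[SubjectMembership]:
    """Mean of each subject's session membership rows (still row-stochastic);
    subjects keep first-appearance order."""
    memberships = np.asarray(memberships, float)
    if memberships.shape[0] != len(subject_ids):
        raise ValueError("one subject id required per membership row")
    order: list[str] = []
    rows: dict[str, list[int]] = {}
    for i, sid in enumerate(subject_ids):
        if sid not in rows:
            rows[sid] = []
            order.append(sid)
        rows[sid].append(i)
    out = []
    for sid in order:
        mean = memberships[rows[sid]].mean(axis=0)
        out.append(SubjectMembership(sid, mean, hard_assign(mean)))
    return out


def profiles_frame(subject_memberships: list[SubjectMembership]) -> pd.DataFrame:
    k = len(subject_memberships[0].membership)
    rows = []
    for sm in subject_memberships:
        row = {"subject_id": sm.subject_id}
        row.update({f"u_{c + 1}": sm.membership[c] for c in range(k)})
        row["hard_cluster"] = sm.hard_cluster
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Validity indices
# ---------------------------------------------------------------------------

def inertia(X: np.ndarray, prototypes: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squared distances to prototypes."""
    d2 = euclidean_distances(X, prototypes, squared=True)
    return float(d2[np.arange(len(X)), np.asarray(labels) - 1].sum())


def spherical_bic(X: np.ndarray, prototypes: np.ndarray, labels: np.ndarray) -> float:
    """BIC under a spherical-Gaussian per-cluster model (x-means style);
    meaningful only for relative comparison across k on the same data."""
    X = np.asarray(X, float)
    n, d = X.shape
    labels = np.asarray(labels)
    k = prototypes.shape[0]
    wss = inertia(X, prototypes, labels)
    sigma2 = max(wss / (d * max(n - k, 1)), 1e-300)
    loglik = 0.0
    for c in range(1, k + 1):
        nc = int((labels == c).sum())
        if nc > 0:
            loglik += nc * np.log(nc / n)
    loglik -= 0.5 * n * d * np.log(2 * np.pi * sigma2)
    loglik -= 0.5 * d * (n - k)
    n_params = k * d + k - 1 + 1
    return float(-2 * loglik + n_params * np.log(n))


def validity_scan(X: np.ndarray, algorithms: tuple[str, ...] = ("fcm", "spectral"),
                  k_range: range = range(2, 7), seed: int = 0,
                  m: float = 1.7) -> pd.DataFrame:
    """Internal validity indices (silhouette, Davies-Bouldin,
    Calinski-Harabasz, spherical BIC, inertia) for every algorithm x k on
    hard labels. Homogeneous clusterings show low DB/BIC/inertia and high
    silhouette/CH. The scan reports the table and an elbow suggestion but
    never fixes k -- that remains a config input."""
    X = np.asarray(X, float)
    rows = []
    for algo in algorithms:
        for k in k_range:
            if not 2 <= k <= len(X) - 1:
                raise ValueError("k_range must lie within [2, N-1]")
            model = fit_model(X, algo, k, seed=seed, m=m)
            labels = model.hard_labels
            n_unique = len(np.unique(labels))
            row = dict(algorithm=algo, k=k,
                       param=m if algo == "fcm" else k,
                       inertia=inertia(X, model.prototypes, labels),
                       bic=spherical_bic(X, model.prototypes, labels))
            if n_unique >= 2:
                row["silhouette"] = float(silhouette_score(X, labels))
                row["davies_bouldin"] = float(davies_bouldin_score(X, labels))
                row["calinski_harabasz"] = float(calinski_harabasz_score(X, labels))
            else:
                row.update(silhouette=np.nan, davies_bouldin=np.nan,
                           calinski_harabasz=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def suggest_elbow(k_values: np.ndarray, scores: np.ndarray) -> int:
    """Simple knee locator: the k with the largest perpendicular distance to
    the chord joining the first and last points of the (k, score) curve."""
    k_values = np.asarray(k_values, float)
    scores = np.asarray(scores, float)
    span = scores.max() - scores.min()
    y = (scores - scores.min()) / (span if span > 0 else 1.0)
    x = (k_values - k_values.min()) / (k_values.max() - k_values.min())
    p0, p1 = np.array([x[0], y[0]]), np.array([x[-1], y[-1]])
    chord = p1 - p0
    chord /= np.linalg.norm(chord)
    pts = np.stack([x, y], axis=1) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0])
    return int(k_values[dist.argmax()])


def match_labels(reference: np.ndarray, candidate: np.ndarray) -> np.ndarray:
    """Relabel ``candidate`` (1..k) to maximize agreement with ``reference``
    via Hungarian matching on the confusion matrix."""
    reference = np.asarray(reference)
    candidate = np.asarray(candidate)
    k = int(max(reference.max(), candidate.max()))
    conf = np.zeros((k, k))
    for r, c in zip(reference, candidate):
        conf[r - 1, c - 1] += 1
    row, col = linear_sum_assignment(-conf)
    mapping = {c + 1: r + 1 for r, c in zip(row, col)}
    return np.array([mapping[c] for c in candidate])
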