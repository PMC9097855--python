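"""Population-level fiber clustering and the compositional connectome.

A subject's tractogram is reduced to the two 3-D endpoints of each
streamline.  Endpoints of all subjects are pooled into a single 6 x M
matrix, clustered with mini-batch K-means in 6-D Euclidean space, and each
subject's connectome is the length-K vector of fiber *proportions* across
the population clusters:

    omega_ik = (# fibers of subject i in cluster k) / m_i

so every row of the resulting matrix lies on the probability simplex.  The
representation is deliberately scale-free: doubling a subject's fiber count
leaves omega unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FiberSet",
    "EndpointMatrix",
    "ClusterModel",
    "ConnectomeMatrix",
    "canonical_endpoints",
    "pool_fibers",
    "fit_clusters",
    "assign",
    "connectome_weights",
]


@dataclass
class FiberSet:
    """All streamlines of one subject.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    fibers : list of ndarray
        Each fiber is an ``(n_points, 3)`` array of mm coordinates with at
        least two points (the two endpoints).
    """

    subject_id: str
    fibers: list[np.ndarray]

    def __post_init__(self) -> None:
        self.fibers = [np.asarray(f, dtype=float) for f in self.fibers]
        for j, f in enumerate(self.fibers):
            if f.ndim != 2 or f.shape[1] != 3 or f.shape[0] < 2:
                raise ValueError(
                    f"fiber {j} of subject {self.subject_id!r} must be an "
                    f"(n_points>=2, 3) array, got shape {f.shape}"
                )

    @property
    def m_i(self) -> int:
        """Number of fibers of this subject."""
        return len(self.fibers)


@dataclass
class EndpointMatrix:
    """Pooled canonical endpoint pairs of a population.

    ``vectors`` is ``6 x M`` where ``M = sum_i m_i``; column j holds the
    stacked pair ``(a, b)`` of fiber j's endpoints.  ``subject_index`` gives
    the owning subject of each column, in the block order the fiber sets
    were supplied.
    """

    vectors: np.ndarray
    subject_index: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.subject_index = np.asarray(self.subject_index)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != 6:
            raise ValueError("vectors must be a 6 x M array")
        if self.subject_index.shape[0] != self.vectors.shape[1]:
            raise ValueError("subject_index length must equal the column count")

    @property
    def n_fibers(self) -> int:
        return self.vectors.shape[1]


@dataclass
class ClusterModel:
    """Fitted mini-batch K-means model over pooled endpoint vectors."""

    K: int
    centroids: np.ndarray  # (K, 6)
    batch_size: int
    n_iter: int
    seed: int
    inertia: float

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if self.centroids.shape != (self.K, 6):
            raise ValueError("centroids must have shape (K, 6)")


@dataclass
class ConnectomeMatrix:
    """n x K compositional connectome; each row is on the simplex."""

    weights: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be 2-D (n_subjects x K)")
        if not self.subject_ids:
            self.subject_ids = [f"sub{i:05d}" for i in range(self.weights.shape[0])]
        if len(self.subject_ids) != self.weights.shape[0]:
            raise ValueError("subject_ids length must match the row count")
        if np.any(self.weights < -1e-12):
            raise ValueError("connectome weights must be nonnegative")
        sums = self.weights.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("each connectome row must sum to 1 (within 1e-9)")

    @property
    def K(self) -> int:
        return self.weights.shape[1]

    @property
    def n_subjects(self) -> int:
        return self.weights.shape[0]


def canonical_endpoints(fiber: np.ndarray) -> np.ndarray:
    """Reduce one streamline to its ordered endpoint pair.

    The first and last points are reordered so the lexicographically
    smaller point (compare x, then y, then z) comes first, which makes the
    representation invariant to the direction the streamline was tracked.

    Returns
    -------
    ndarray, shape (6,)
        ``(p, q)`` concatenated, with ``p <= q`` lexicographically.
    """
    f = np.asarray(fiber, dtype=float)
    if f.ndim != 2 or f.shape[0] < 2 or f.shape[1] != 3:
        raise ValueError("fiber must be an (n_points>=2, 3) array")
    p, q = f[0], f[-1]
    if tuple(q) < tuple(p):
        p, q = q, p
    return np.concatenate([p, q])


def pool_fibers(fiber_sets: list[FiberSet]) -> EndpointMatrix:
    """Stack canonical endpoint vectors of all subjects into one matrix.

    Columns appear per subject in input order; the column count equals the
    total fiber count across subjects.
    """
    fiber_sets = list(fiber_sets)
    if not fiber_sets or all(fs.m_i == 0 for fs in fiber_sets):
        raise ValueError("pool_fibers requires at least one non-empty FiberSet")
    cols = []
    owners = []
    for fs in fiber_sets:
        for f in fs.fibers:
            cols.append(canonical_endpoints(f))
            owners.append(fs.subject_id)
    return EndpointMatrix(np.array(cols).T, np.array(owners, dtype=object))


def _kmeans_plusplus(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Standard k-means++ seeding (D^2 sampling) on row-wise data."""
    M = X.shape[0]
    centers = np.empty((K, X.shape[1]))
    centers[0] = X[rng.integers(M)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0.0:
            # all remaining mass at already-chosen points: pick uniformly
            idx = rng.integers(M)
        else:
            idx = rng.choice(M, p=d2 / total)
        centers[k] = X[idx]
        d2 = np.minimum(d2, np.sum((X - centers[k]) ** 2, axis=1))
    return centers


def fit_clusters(
    C: EndpointMatrix,
    K: int,
    batch_size: int = 1024,
    n_iter: int = 200,
    seed: int = 0,
) -> ClusterModel:
    """Mini-batch K-means over the pooled endpoint matrix.

    The model is fitted once on the whole population and reused.  Each
    iteration draws a uniform batch (without replacement, capped at the
    sample count), assigns it to the nearest centroids, and moves every
    touched centroid with the streaming per-centre learning rate
    ``1 / cumulative assignment count``.  With ``batch_size >= M`` and
    ``K = 1`` the centroid is therefore exactly the data mean.

    After fitting, clusters are relabeled by descending total fiber mass so
    labels are stable across runs; the labels themselves carry no anatomical
    meaning.
    """
    X = C.vectors.T  # (M, 6)
    M = X.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > M:
        raise ValueError(f"K={K} exceeds the number of fibers ({M})")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rng = np.random.default_rng(seed)

    centroids = _kmeans_plusplus(X, K, rng)
    counts = np.zeros(K, dtype=np.int64)
    b = min(batch_size, M)
    for _ in range(n_iter):
        idx = rng.choice(M, size=b, replace=False) if b < M else np.arange(M)
        batch = X[idx]
        d2 = ((batch[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)
        nb = np.bincount(labels, minlength=K)
        sums = np.zeros_like(centroids)
        np.add.at(sums, labels, batch)
        touched = nb > 0
        new_counts = counts[touched] + nb[touched]
        centroids[touched] = (
            counts[touched, None] * centroids[touched] + sums[touched]
        ) / new_counts[:, None]
        counts[touched] = new_counts

    # re-seed clusters that never received a point from the farthest point
    if np.any(counts == 0):
        d2_full = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        nearest = d2_full.min(axis=1)
        for k in np.flatnonzero(counts == 0):
            far = int(np.argmax(nearest))
            logger.warning("cluster %d was empty; re-seeded from farthest point", k)
            centroids[k] = X[far]
            d2_full[:, k] = ((X - centroids[k]) ** 2).sum(axis=1)
            nearest = d2_full.min(axis=1)

    # deterministic relabeling: descending total mass on the full data
    d2_full = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    full_labels = np.argmin(d2_full, axis=1)
    mass = np.bincount(full_labels, minlength=K)
    order = np.argsort(-mass, kind="stable")
    centroids = centroids[order]

    d2_final = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    inertia = float(d2_final.min(axis=1).sum())
    return ClusterModel(
        K=K,
        centroids=centroids,
        batch_size=batch_size,
        n_iter=n_iter,
        seed=seed,
        inertia=inertia,
    )


def assign(model: ClusterModel, C: EndpointMatrix) -> np.ndarray:
    """Label every fiber with its nearest centroid (Euclidean).

    Ties are broken toward the lowest cluster index.
    """
    X = C.vectors.T
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError("dimension mismatch between model and endpoint matrix")
    d2 = ((X[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def connectome_weights(
    labels: np.ndarray, subject_index: np.ndarray, K: int
) -> ConnectomeMatrix:
    """Per-subject fiber proportions across the K population clusters.

    ``omega_ik`` is the fraction of subject i's fibers carrying label k;
    rows sum to one exactly.  Subjects appear in order of first appearance
    in ``subject_index``.
    """
    labels = np.asarray(labels)
    subject_index = np.asarray(subject_index)
    if labels.shape != subject_index.shape:
        raise ValueError("labels and subject_index must have equal length")
    if labels.size and (labels.min() < 0 or labels.max() >= K):
        raise ValueError("labels must lie in [0, K)")
    subjects = list(dict.fromkeys(subject_index.tolist()))
    W = np.zeros((len(subjects), K))
    for i, sid in enumerate(subjects):
        lab = labels[subject_index == sid]
        if lab.size == 0:
            raise ValueError(f"subject {sid!r} has zero fibers")
        W[i] = np.bincount(lab, minlength=K) / lab.size
    return ConnectomeMatrix(W, [str(s) for s in subjects])
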