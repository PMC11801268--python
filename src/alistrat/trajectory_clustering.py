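"""Stratification of PT% trajectories by dynamic-time-warping k-means.

Trajectories are clustered on the raw PT% scale (absolute level is clinically
meaningful) using classic DTW with squared local cost, DBA (DTW barycenter
averaging) centroids, and restart-based k-means.  With k=6 the clusters are
deterministically relabeled G1..G6 by descending time-average centroid PT%,
matching the clinical convention that G1 is the mildest (high-stable) and G6
the most severe (low non-recovering) stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClusterResult",
    "dtw_distance",
    "dba_barycenter",
    "cluster_trajectories",
    "elbow_curve",
    "relabel_groups",
]


@dataclass
class ClusterResult:
    labels: np.ndarray          # per-patient cluster index, 0..k-1
    centroids: np.ndarray       # k x T
    inertia: float              # sum of within-cluster DTW distances
    k: int
    group_names: list[str] | None = None  # set by relabel_groups

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if self.inertia < 0:
            raise ValueError("inertia must be >= 0")
        counts = np.bincount(self.labels, minlength=self.k)
        if np.any(counts == 0):
            raise ValueError("every cluster must be nonempty")

    def named_labels(self) -> list[str]:
        names = self.group_names or [f"C{i + 1}" for i in range(self.k)]
        return [names[i] for i in self.labels]


def dtw_distance(a, b, window: int | None = None) -> float:
    """Classic DTW with squared-difference local cost.

    Dynamic program over the step set {(1,0), (0,1), (1,1)}; returns the
    optimal accumulated cost.  ``window`` is a Sakoe–Chiba band half-width
    (``window=0`` on equal-length series forces the diagonal, i.e. the sum
    of squared pointwise differences).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("series must be nonempty")
    if window is not None and window < 0:
        raise ValueError("window must be >= 0")
    n, m = a.size, b.size
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        if window is None:
            j_lo, j_hi = 1, m
        else:
            # Band around the stretched diagonal.
            center = (i - 1) * (m - 1) / max(n - 1, 1)
            j_lo = max(1, int(np.ceil(center - window)) + 1)
            j_hi = min(m, int(np.floor(center + window)) + 1)
        for j in range(j_lo, j_hi + 1):
            cost = (a[i - 1] - b[j - 1]) ** 2
            acc[i, j] = cost + min(acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1])
    return float(acc[n, m])


def _dtw_path(a: np.ndarray, b: np.ndarray) -> list[tuple[int, int]]:
    """Optimal warping path (index pairs), ties broken toward the diagonal."""
    n, m = a.size, b.size
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            acc[i, j] = (a[i - 1] - b[j - 1]) ** 2 + min(
                acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
            )
    path = []
    i, j = n, m
    while i > 0 and j > 0:
        path.append((i - 1, j - 1))
        moves = [(acc[i - 1, j - 1], i - 1, j - 1), (acc[i - 1, j], i - 1, j),
                 (acc[i, j - 1], i, j - 1)]
        _, i, j = min(moves, key=lambda x: x[0])
    path.reverse()
    return path


def dba_barycenter(series, max_iter: int = 30, seed: int = 0, init=None) -> np.ndarray:
    """DTW barycenter averaging.

    Iteratively aligns every series to the current centroid and replaces each
    centroid point by the mean of the values aligned to it; the total DTW
    cost to the centroid is non-increasing and iteration stops at ``max_iter``
    or when the relative improvement falls below 1e-6.
    """
    X = np.asarray(series, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("series must be a nonempty set of equal-length series")
    centroid = np.asarray(init, dtype=float).copy() if init is not None else X[0].copy()
    prev_cost = np.inf
    for _ in range(max_iter):
        sums = np.zeros_like(centroid)
        counts = np.zeros_like(centroid)
        cost = 0.0
        for x in X:
            path = _dtw_path(centroid, x)
            for ci, xi in path:
                sums[ci] += x[xi]
                counts[ci] += 1
                cost += (centroid[ci] - x[xi]) ** 2
        new = np.where(counts > 0, sums / np.maximum(counts, 1), centroid)
        if prev_cost - cost < 1e-6 * max(prev_cost, 1.0):
            centroid = new
            break
        centroid = new
        prev_cost = cost
    return centroid


def _kmeanspp_init(X: np.ndarray, k: int, rng, window=None) -> np.ndarray:
    """k-means++ seeding under the DTW metric (far-apart initial centroids)."""
    n = X.shape[0]
    chosen = [int(rng.integers(n))]
    d2 = np.array([dtw_distance(x, X[chosen[0]], window=window) for x in X])
    while len(chosen) < k:
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        nxt = int(rng.choice(n, p=probs))
        chosen.append(nxt)
        d_new = np.array([dtw_distance(x, X[nxt], window=window) for x in X])
        d2 = np.minimum(d2, d_new)
    return X[chosen].copy()


def _assign(X: np.ndarray, centroids: np.ndarray, window=None):
    n, k = X.shape[0], centroids.shape[0]
    d = np.empty((n, k))
    for j in range(k):
        for i in range(n):
            d[i, j] = dtw_distance(X[i], centroids[j], window=window)
    labels = d.argmin(axis=1)
    return labels, d[np.arange(n), labels].sum(), d


def cluster_trajectories(
    matrix, k: int, n_init: int = 10, seed: int = 0, max_iter: int = 20, window=None
) -> ClusterResult:
    """k-means in DTW space with DBA centroids and random restarts.

    Raw PT% values are clustered (no normalization).  ``n_init`` restarts
    with distinct centroid seeds; the solution with the lowest sum of
    within-cluster DTW distances is kept.  An empty cluster is reseeded from
    the point farthest from its centroid.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError("need n >= k >= 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centroids = _kmeanspp_init(X, k, rng, window)
        labels = None
        for _ in range(max_iter):
            labels, inertia, dmat = _assign(X, centroids, window)
            # Reseed empty clusters from the farthest point.
            for j in range(k):
                if not np.any(labels == j):
                    far = np.argmax(dmat[np.arange(n), labels])
                    labels[far] = j
            new_centroids = np.vstack(
                [dba_barycenter(X[labels == j], seed=seed, init=centroids[j]) for j in range(k)]
            )
            if np.allclose(new_centroids, centroids, atol=1e-8):
                centroids = new_centroids
                break
            centroids = new_centroids
        labels, inertia, _ = _assign(X, centroids, window)
        for j in range(k):
            if not np.any(labels == j):
                far = np.argmax([dtw_distance(X[i], centroids[labels[i]]) for i in range(n)])
                labels[far] = j
        if best is None or inertia < best.inertia:
            best = ClusterResult(labels=labels, centroids=centroids, inertia=float(inertia), k=k)
    return best


def elbow_curve(matrix, k_range, seed: int = 0, n_init: int = 5) -> list[tuple[int, float]]:
    """Within-cluster DTW inertia for each k (diagnostic elbow output)."""
    return [
        (int(k), cluster_trajectories(matrix, int(k), n_init=n_init, seed=seed).inertia)
        for k in k_range
    ]


def relabel_groups(result: ClusterResult) -> ClusterResult:
    """Deterministic clinical naming of clusters.

    With k=6 the clusters are named G1..G6 in order of descending centroid
    time-average PT% (ties broken by day-0 centroid value, descending);
    other k get generic names C1..Ck under the same ordering.  The labels
    and centroid rows are permuted into that canonical order.
    """
    means = result.centroids.mean(axis=1)
    day0 = result.centroids[:, 0]
    order = sorted(range(result.k), key=lambda j: (-means[j], -day0[j]))
    prefix = "G" if result.k == 6 else "C"
    names = [f"{prefix}{i + 1}" for i in range(result.k)]
    remap = np.empty(result.k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    return ClusterResult(
        labels=remap[result.labels],
        centroids=result.centroids[order],
        inertia=result.inertia,
        k=result.k,
        group_names=names,
    )
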