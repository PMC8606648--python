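"""K-means on 2-D cell locations, in the matrix-factorization form.

Lloyd's algorithm on squared Euclidean distance clusters the location
matrix ``L`` (2 x n).  In matrix form the objective is
``|| L - W_L @ H_L ||_F^2`` with ``W_L`` the 2 x k centroids and ``H_L``
a binary indicator with exactly one 1 per column — identical to the
within-cluster sum of squares (WCSS).

The location clustering also yields a *confidence matrix* ``H_hat``
(k x n) used by the consensus solver: for each cell only the rows of
its two nearest centroids are nonzero, with values proportional to the
distance to each of those centroids (so the two entries of a column sum
to one).  Its complement ``C = 1 - H_hat`` weights the consensus
penalty.  The distance-proportional weighting gives the *farther* of
the two nearest centroids the larger score; ``invert=True`` computes
the complementary closer-is-larger variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "KMeansResult",
    "ConfidenceMatrix",
    "SpatialKMeans",
    "centroids_from_labels",
    "kmeans_locations",
    "confidence_matrix",
]


@dataclass
class KMeansResult:
    W_L: np.ndarray  # (2, k) centroids
    H_L: np.ndarray  # (k, n) binary indicator, one 1 per column
    labels: np.ndarray  # (n,) in {1..k}
    wcss: float
    n_iter: int
    wcss_trace: list[float] = field(default_factory=list)


@dataclass
class ConfidenceMatrix:
    H_hat: np.ndarray  # (k, n), two nonzeros per column summing to 1
    C: np.ndarray  # 1 - H_hat, entries in [0, 1]


def _check_locations(L: np.ndarray) -> np.ndarray:
    L = np.asarray(L, dtype=float)
    if L.ndim != 2 or L.shape[0] != 2:
        raise ValueError("locations must be a 2 x n matrix")
    if L.shape[1] == 0:
        raise ValueError("no cells in location matrix")
    if not np.isfinite(L).all():
        raise ValueError("locations must be finite")
    return L


def _sq_dists(L: np.ndarray, W: np.ndarray) -> np.ndarray:
    """(k, n) squared distances between centroids W (2,k) and cells L (2,n)."""
    diff = W.T[:, :, None] - L[None, :, :]
    return np.sum(diff * diff, axis=1)


def centroids_from_labels(
    L: np.ndarray, labels: np.ndarray, k: int
) -> np.ndarray:
    """Per-cluster coordinate means; empty clusters re-seed at the cell
    farthest from its own centroid (each re-seed consumes that cell so two
    empty clusters never land on the same point)."""
    L = _check_locations(L)
    labels = np.asarray(labels, dtype=int)
    if labels.min(initial=1) < 1 or labels.max(initial=k) > k:
        raise ValueError("labels must lie in {1..k}")
    n = L.shape[1]
    W = np.zeros((2, k))
    empty = []
    for j in range(1, k + 1):
        mask = labels == j
        if mask.any():
            W[:, j - 1] = L[:, mask].mean(axis=1)
        else:
            empty.append(j - 1)
    if empty:
        # distance of each cell to its assigned (non-empty) centroid
        d_own = np.linalg.norm(L - W[:, labels - 1], axis=0)
        taken: list[int] = []
        for j in empty:
            order = np.argsort(-d_own)
            pick = next(int(i) for i in order if i not in taken)
            W[:, j] = L[:, pick]
            taken.append(pick)
            d_own[pick] = -np.inf
    return W


def kmeans_locations(
    L: np.ndarray,
    k: int,
    init_centroids: np.ndarray,
    max_iter: int = 300,
) -> KMeansResult:
    """Lloyd iteration from a fixed initialization.

    Assignment ties break toward the lower centroid index; iteration
    stops when labels no longer change or after ``max_iter`` sweeps.
    """
    L = _check_locations(L)
    n = L.shape[1]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} must be in [1, n={n}]")
    W = np.asarray(init_centroids, dtype=float)
    if W.shape != (2, k) or not np.isfinite(W).all():
        raise ValueError("init_centroids must be a finite 2 x k matrix")

    labels = np.zeros(n, dtype=int)
    trace: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = _sq_dists(L, W)
        new_labels = d2.argmin(axis=0) + 1
        trace.append(float(d2[new_labels - 1, np.arange(n)].sum()))
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        W = centroids_from_labels(L, labels, k)

    H_L = np.zeros((k, n))
    H_L[labels - 1, np.arange(n)] = 1.0
    wcss = float(np.sum((L - W @ H_L) ** 2))
    return KMeansResult(
        W_L=W, H_L=H_L, labels=labels, wcss=wcss, n_iter=n_iter,
        wcss_trace=trace,
    )


def confidence_matrix(
    L: np.ndarray, W_L: np.ndarray, invert: bool = False
) -> ConfidenceMatrix:
    """Location-confidence scores over each cell's two nearest centroids.

    For cell ``i`` with nearest centroids ``j1, j2`` at distances
    ``d1 <= d2``, the default sets ``H_hat[j, i] = d_j / (d1 + d2)`` for
    ``j in {j1, j2}`` (distance-proportional, as in the model's stated
    form); ``invert=True`` swaps the two weights so the closer centroid
    scores higher.  A cell coincident with both nearest centroids gets
    0.5/0.5.  Ties in nearness break toward the lower centroid index.
    """
    L = _check_locations(L)
    W_L = np.asarray(W_L, dtype=float)
    k = W_L.shape[1]
    if k < 2:
        raise ValueError("confidence matrix needs k >= 2 centroids")
    n = L.shape[1]
    d = np.sqrt(_sq_dists(L, W_L))
    # argsort is stable -> nearest-centroid ties resolve to the lower index
    order = np.argsort(d, axis=0, kind="stable")
    j1, j2 = order[0], order[1]
    cols = np.arange(n)
    d1, d2 = d[j1, cols], d[j2, cols]
    denom = d1 + d2
    w1 = np.full(n, 0.5)
    np.divide(d1, denom, where=denom > 0, out=w1)
    w2 = 1.0 - w1
    if invert:
        w1, w2 = w2, w1
    H_hat = np.zeros((k, n))
    H_hat[j1, cols] = w1
    H_hat[j2, cols] = w2
    return ConfidenceMatrix(H_hat=H_hat, C=1.0 - H_hat)


class SpatialKMeans(ClusterMixin, BaseEstimator):
    """K-means clustering of 2-D cell locations (scikit-learn style).

    ``X`` is (n_cells, 2).  ``init`` may be a (k, 2) centroid array or
    ``"random"`` (k distinct cells chosen with ``random_state``).
    Fitted attributes: ``cluster_centers_`` (k, 2), ``labels_`` in
    {1..k}, ``inertia_`` (the WCSS), ``n_iter_``, and ``confidence_``
    (set by :meth:`confidence`).
    """

    def __init__(
        self,
        n_clusters: int = 6,
        *,
        init: np.ndarray | str = "random",
        max_iter: int = 300,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.init = init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_cells, 2)")
        L = X.T
        k = int(self.n_clusters)
        if isinstance(self.init, str):
            if self.init != "random":
                raise ValueError("init must be 'random' or a (k, 2) array")
            rng = np.random.default_rng(self.random_state)
            idx = rng.choice(X.shape[0], size=k, replace=False)
            init = L[:, idx]
        else:
            init = np.asarray(self.init, dtype=float).T
        res = kmeans_locations(L, k, init, max_iter=self.max_iter)
        self.cluster_centers_ = res.W_L.T
        self.labels_ = res.labels
        self.inertia_ = res.wcss
        self.n_iter_ = res.n_iter
        self.result_ = res
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d2 = _sq_dists(X.T, self.cluster_centers_.T)
        return d2.argmin(axis=0) + 1

    def confidence(self, X, invert: bool = False) -> ConfidenceMatrix:
        """Top-2 confidence matrix of cells ``X`` against the fitted centroids."""
        return confidence_matrix(
            np.asarray(X, dtype=float).T, self.cluster_centers_.T, invert=invert
        )
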