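"""Consensus clustering of expression and location: the hybrid solver.

Starting from sparse NMF factors ``(W, H)`` of the expression matrix
``A`` and a location k-means whose centroids yield the top-2 confidence
matrix ``H_hat`` (complement ``C = 1 - H_hat``), the solver minimizes

    g(W, H) = || A - W H ||_F^2  +  alpha * || H - H o H_hat ||_F^2 ,

where ``o`` is the elementwise product.  Because ``H_hat`` has entries
in [0, 1], the penalty equals ``|| H o C ||_F^2``: membership mass on
rows where the location clustering is confident (``C`` small) is cheap,
mass elsewhere is penalized, with ``alpha`` controlling how strongly
the location clusters steer the expression-based memberships.

Optimization is two-block coordinate descent with exact NNLS solves:

* ``H``-step — column ``i`` solves the stacked system
  ``min_{h>=0} || [W; sqrt(alpha) diag(C[:, i])] h - [A[:, i]; 0] ||``
  (columns are independent);
* ``W``-step — the transposed NNLS ``min_{W>=0} || H^T W^T - A^T ||``.

Each half-step solves its block exactly, so the objective is
non-increasing and every limit point is a stationary point of ``g``.
Termination uses a normalized projected-gradient KKT residual (relative
to the residual after the first iteration) with threshold ``tol``
(default 0.01), alongside a ``max_iter`` cap (default 500).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .solvers import nnls_columns, nnls_columns_penalized
from .sparse_nmf import SparseNMFConfig, hard_assign, normalize_factors, sparse_nmf
from .spatial_kmeans import centroids_from_labels, confidence_matrix, kmeans_locations

__all__ = [
    "HybridConfig",
    "ClusterResult",
    "SCHybridNMF",
    "objective",
    "update_H",
    "update_W",
    "kkt_residual",
    "run_schybridnmf",
]


@dataclass
class HybridConfig:
    """Consensus-stage parameters.

    alpha : weight of the consensus penalty (0 recovers plain NMF ANLS).
    tol : threshold on the normalized KKT residual (default 0.01).
    max_iter : BCD sweep cap, set high so the KKT check triggers first.
    invert_confidence : closer-centroid-scores-higher variant of H_hat.
    """

    alpha: float = 1.0
    tol: float = 0.01
    max_iter: int = 500
    invert_confidence: bool = False
    seed: int = 0


@dataclass
class ClusterResult:
    labels: np.ndarray  # (n,) in {1..k}
    W_A: np.ndarray  # (m, k)
    H_A: np.ndarray  # (k, n)
    objective_trace: list[float]
    termination: str  # "kkt_converged" | "max_iter"
    n_iter: int
    config: dict[str, Any] = field(default_factory=dict)
    nmf_labels: np.ndarray | None = None
    kmeans_labels: np.ndarray | None = None


def _check_conform(A, W, H, H_hat_or_C):
    A = np.asarray(A, dtype=float)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    S = np.asarray(H_hat_or_C, dtype=float)
    m, n = A.shape
    k = W.shape[1]
    if W.shape != (m, k) or H.shape != (k, n) or S.shape != (k, n):
        raise ValueError(
            f"shape mismatch: A{A.shape}, W{W.shape}, H{H.shape}, aux{S.shape}"
        )
    return A, W, H, S


def objective(A, W_A, H_A, H_hat, alpha: float) -> float:
    """Consensus objective ``||A - W H||_F^2 + alpha ||H - H o H_hat||_F^2``.

    The penalty term is also evaluated through its complement identity
    ``||H o (1 - H_hat)||_F^2`` and the two routes are asserted to agree.
    """
    A, W, H, H_hat = _check_conform(A, W_A, H_A, H_hat)
    r = A - W @ H
    fit = float(np.sum(r * r))
    direct = float(np.sum((H - H * H_hat) ** 2))
    via_c = float(np.sum((H * (1.0 - H_hat)) ** 2))
    assert abs(direct - via_c) <= 1e-9 * max(1.0, direct)
    return fit + alpha * direct


def update_H(A, W_A, C, alpha: float) -> np.ndarray:
    """Exact consensus H-step: per-column stacked NNLS with diag(C[:, i])."""
    A, W, _, C = _check_conform(A, W_A, np.zeros((W_A.shape[1], A.shape[1])), C)
    if alpha == 0:
        return nnls_columns(W, A)
    return nnls_columns_penalized(W, A, C, alpha)


def update_W(A, H_A) -> np.ndarray:
    """Exact W-step: NNLS on the transposed system."""
    A = np.asarray(A, dtype=float)
    H = np.asarray(H_A, dtype=float)
    return nnls_columns(H.T, A.T).T


def _kkt_raw(A, W, H, C, alpha: float) -> float:
    """Unnormalized projected-gradient KKT residual (RMS of violations)."""
    R = W @ H - A
    gW = 2.0 * (R @ H.T)
    gH = 2.0 * (W.T @ R + alpha * (C * C) * H)
    vW = np.where(W > 0, gW, np.minimum(gW, 0.0))
    vH = np.where(H > 0, gH, np.minimum(gH, 0.0))
    total = float(np.sum(vW * vW) + np.sum(vH * vH))
    return np.sqrt(total / (vW.size + vH.size))


def kkt_residual(A, W_A, H_A, C, alpha: float, first_residual: float | None = None) -> float:
    """Normalized KKT residual of the consensus objective.

    Gradient entries count where the factor entry is positive; where it
    is zero only a negative gradient counts (a descent direction blocked
    by the constraint).  The RMS of those violations is divided by
    ``first_residual`` (the value after the first BCD sweep) when given,
    so the iteration-1 value is exactly 1.
    """
    A, W, H, C = _check_conform(A, W_A, H_A, C)
    raw = _kkt_raw(A, W, H, C, alpha)
    if first_residual is None:
        return raw
    if first_residual == 0:
        return 0.0
    return raw / first_residual


def _bcd(A, W, H, H_hat, C, alpha, tol, max_iter):
    """Block coordinate descent loop; returns factors, traces, termination."""
    trace = [objective(A, W, H, H_hat, alpha)]
    halves: list[tuple[float, float]] = []
    kkt_trace: list[float] = []
    termination = "max_iter"
    rho1 = None
    it = 0
    for it in range(1, max_iter + 1):
        H = update_H(A, W, C, alpha)
        obj_h = objective(A, W, H, H_hat, alpha)
        W = update_W(A, H)
        obj_w = objective(A, W, H, H_hat, alpha)
        halves.append((obj_h, obj_w))
        trace.append(obj_w)
        rho = _kkt_raw(A, W, H, C, alpha)
        if it == 1:
            rho1 = rho
        norm = 0.0 if rho1 == 0 else rho / rho1
        kkt_trace.append(norm)
        if it > 1 and norm < tol:
            termination = "kkt_converged"
            break
        if rho1 == 0:  # already stationary after the first sweep
            termination = "kkt_converged"
            break
    return W, H, trace, halves, kkt_trace, termination, it


class SCHybridNMF(ClusterMixin, BaseEstimator):
    """Hybrid expression + location clustering (scikit-learn style).

    ``fit(X, locations=L)`` takes ``X`` as (n_cells, n_genes) nonnegative
    expression and ``L`` as (n_cells, 2) coordinates; alternatively ``X``
    may be an AnnData whose ``.X`` is expression and whose
    ``.obsm["spatial"]`` holds the coordinates.

    Pipeline: sparse NMF on expression -> hard labels -> location
    centroids from those labels -> Lloyd k-means -> top-2 confidence
    matrix -> block coordinate descent on the consensus objective.

    Fitted attributes
    -----------------
    labels_ : final hard labels in {1..k}.
    W_, H_ : final factors (genes x k, k x cells).
    nmf_labels_, kmeans_labels_ : labels of the two initial stages
        (exactly the instances used inside the pipeline).
    confidence_, complement_ : H_hat and C = 1 - H_hat.
    objective_trace_, objective_halfsteps_, kkt_trace_ : diagnostics.
    termination_ : "kkt_converged" or "max_iter"; n_iter_ : BCD sweeps.
    """

    def __init__(
        self,
        n_clusters: int = 6,
        *,
        alpha: float = 1.0,
        tol: float = 0.01,
        max_iter: int = 500,
        invert_confidence: bool = False,
        nmf_beta: float | str = "auto",
        nmf_gamma: float | str = "auto",
        nmf_max_iter: int = 200,
        nmf_tol: float = 1e-4,
        kmeans_max_iter: int = 300,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter
        self.invert_confidence = invert_confidence
        self.nmf_beta = nmf_beta
        self.nmf_gamma = nmf_gamma
        self.nmf_max_iter = nmf_max_iter
        self.nmf_tol = nmf_tol
        self.kmeans_max_iter = kmeans_max_iter
        self.random_state = random_state

    def _unpack(self, X, locations):
        if hasattr(X, "obsm") and hasattr(X, "X"):  # AnnData duck-typing
            if locations is None:
                if "spatial" not in X.obsm:
                    raise ValueError("AnnData input needs obsm['spatial']")
                locations = np.asarray(X.obsm["spatial"])
            X = np.asarray(
                X.X.toarray() if hasattr(X.X, "toarray") else X.X, dtype=float
            )
        if locations is None:
            raise ValueError("locations (n_cells, 2) are required")
        X = np.asarray(X, dtype=float)
        L = np.asarray(locations, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_cells, n_genes)")
        if L.shape != (X.shape[0], 2):
            raise ValueError(
                f"locations must be ({X.shape[0]}, 2), got {L.shape}"
            )
        return X, L

    def fit(self, X, y=None, *, locations=None):
        X, Lrows = self._unpack(X, locations)
        if (X < 0).any() or not np.isfinite(X).all():
            raise ValueError("expression must be nonnegative and finite")
        k = int(self.n_clusters)
        if k < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.alpha < 0 or self.tol <= 0:
            raise ValueError("alpha must be >= 0 and tol > 0")
        A = X.T
        L = Lrows.T

        # stage 1: sparse NMF on expression, normalized factors
        nmf_cfg = SparseNMFConfig(
            k=k,
            beta=None if self.nmf_beta == "auto" else float(self.nmf_beta),
            gamma=None if self.nmf_gamma == "auto" else float(self.nmf_gamma),
            max_iter=self.nmf_max_iter,
            rel_tol=self.nmf_tol,
            seed=self.random_state,
        )
        W, H, nmf_trace = sparse_nmf(A, nmf_cfg)
        nmf_labels = hard_assign(H)

        # stage 2: location k-means seeded from the expression clusters
        init = centroids_from_labels(L, nmf_labels, k)
        km = kmeans_locations(L, k, init, max_iter=self.kmeans_max_iter)

        # stage 3: confidence matrix, held fixed during the descent
        conf = confidence_matrix(L, km.W_L, invert=self.invert_confidence)

        # stage 4: block coordinate descent on the consensus objective
        W, H, trace, halves, kkt_trace, termination, n_iter = _bcd(
            A, W, H, conf.H_hat, conf.C, float(self.alpha), float(self.tol),
            int(self.max_iter),
        )

        self.W_ = W
        self.H_ = H
        self.components_ = W.T
        self.labels_ = hard_assign(H)
        self.nmf_labels_ = nmf_labels
        self.nmf_objective_trace_ = nmf_trace
        self.kmeans_labels_ = km.labels
        self.kmeans_result_ = km
        self.confidence_ = conf.H_hat
        self.complement_ = conf.C
        self.objective_trace_ = trace
        self.objective_halfsteps_ = halves
        self.kkt_trace_ = kkt_trace
        self.termination_ = termination
        self.n_iter_ = n_iter
        return self

    def fit_predict(self, X, y=None, *, locations=None):
        return self.fit(X, locations=locations).labels_


def run_schybridnmf(
    A: np.ndarray,
    L: np.ndarray,
    k: int,
    nmf_config: SparseNMFConfig | None = None,
    hybrid_config: HybridConfig | None = None,
) -> ClusterResult:
    """Functional wrapper over :class:`SCHybridNMF` in paper orientation.

    ``A`` is genes x cells, ``L`` is 2 x n.  Seeds come from the configs
    (the hybrid seed is used when no NMF config is given).
    """
    hybrid_config = hybrid_config or HybridConfig()
    nmf_config = nmf_config or SparseNMFConfig(k=k, seed=hybrid_config.seed)
    if nmf_config.k != k:
        raise ValueError("nmf_config.k must match k")
    est = SCHybridNMF(
        n_clusters=k,
        alpha=hybrid_config.alpha,
        tol=hybrid_config.tol,
        max_iter=hybrid_config.max_iter,
        invert_confidence=hybrid_config.invert_confidence,
        nmf_beta="auto" if nmf_config.beta is None else nmf_config.beta,
        nmf_gamma="auto" if nmf_config.gamma is None else nmf_config.gamma,
        nmf_max_iter=nmf_config.max_iter,
        nmf_tol=nmf_config.rel_tol,
        random_state=nmf_config.seed,
    ).fit(np.asarray(A, dtype=float).T, locations=np.asarray(L, dtype=float).T)
    return ClusterResult(
        labels=est.labels_,
        W_A=est.W_,
        H_A=est.H_,
        objective_trace=est.objective_trace_,
        termination=est.termination_,
        n_iter=est.n_iter_,
        config=est.get_params(),
        nmf_labels=est.nmf_labels_,
        kmeans_labels=est.kmeans_labels_,
    )
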