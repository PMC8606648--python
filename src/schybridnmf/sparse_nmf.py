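"""Sparse nonnegative matrix factorization by alternating NNLS.

Factorizes a nonnegative genes x cells matrix ``A ~ W @ H`` (``W``:
m x k cluster representatives, ``H``: k x n memberships) under the
objective

    || A - W H ||_F^2  +  beta * || W ||_F^2  +  gamma * sum_i || H[:, i] ||_1^2 .

The squared column-l1 penalty pushes each cell's membership toward a
single cluster, so the argmax over each column of ``H`` acts as a hard
assignment.  Both half-steps are exact NNLS solves using the standard
augmented-matrix encoding:

* ``H``-step: stack a row ``sqrt(gamma) * 1_k^T`` under ``W`` with a zero
  appended to each rhs column — this reproduces ``gamma * ||h||_1^2``
  exactly for ``h >= 0``.
* ``W``-step: stack ``sqrt(beta) * I_k`` under ``H^T`` in the transposed
  system.

With exact subproblem solves the objective is non-increasing at every
half-step.  The data-driven defaults ``beta = m / ||A||_F^2`` and
``gamma = n / ||A||_F^2`` keep the penalties proportionate to the
fitting term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .solvers import nnls_columns

__all__ = [
    "SparseNMFConfig",
    "SparseNMF",
    "default_regularization",
    "sparse_nmf",
    "normalize_factors",
    "hard_assign",
]


@dataclass
class SparseNMFConfig:
    """Hyperparameters of the sparse NMF stage.

    ``beta``/``gamma`` of ``None`` mean the data-driven defaults.
    ``rel_tol`` stops the alternation when the relative objective change
    falls below it.
    """

    k: int
    beta: float | None = None
    gamma: float | None = None
    max_iter: int = 200
    rel_tol: float = 1e-4
    seed: int = 0


def default_regularization(A: np.ndarray) -> tuple[float, float]:
    """Data-driven penalties ``beta = m / ||A||_F^2``, ``gamma = n / ||A||_F^2``."""
    A = np.asarray(A, dtype=float)
    fro2 = float(np.sum(A * A))
    if fro2 == 0.0:
        raise ValueError("expression matrix is identically zero")
    m, n = A.shape
    return m / fro2, n / fro2


def normalize_factors(
    W: np.ndarray, H: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Scale each nonzero column of W to unit Euclidean norm, compensating in H.

    The product ``W @ H`` is unchanged.  All-zero columns of ``W`` pass
    through untouched.
    """
    W = np.array(W, dtype=float)
    H = np.array(H, dtype=float)
    norms = np.linalg.norm(W, axis=0)
    nz = norms > 0
    W[:, nz] /= norms[nz]
    H[nz, :] *= norms[nz, None]
    return W, H


def hard_assign(H: np.ndarray) -> np.ndarray:
    """Hard labels in {1..k}: row of the largest entry per column of ``H``.

    Ties break toward the smaller row index.  An all-zero column carries
    no membership information; it is assigned to cluster 1 with a warning.
    """
    H = np.asarray(H, dtype=float)
    dead = ~H.any(axis=0)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} cell(s) have all-zero membership; assigned "
            "to cluster 1",
            RuntimeWarning,
            stacklevel=2,
        )
    return H.argmax(axis=0) + 1


def _objective(A, W, H, beta, gamma) -> float:
    r = A - W @ H
    val = float(np.sum(r * r)) + beta * float(np.sum(W * W))
    if gamma > 0:
        val += gamma * float(np.sum(H.sum(axis=0) ** 2))
    return val


def _anls(A, k, beta, gamma, max_iter, rel_tol, rng):
    m, n = A.shape
    scale = np.sqrt(max(A.mean(), np.finfo(float).tiny) / k)
    W = rng.uniform(0.0, 1.0, size=(m, k)) * scale
    H = rng.uniform(0.0, 1.0, size=(k, n)) * scale

    sqrt_g = np.sqrt(gamma)
    sqrt_b = np.sqrt(beta)
    eye = np.eye(k)
    zeros_row = np.zeros((1, n))
    zeros_blk = np.zeros((k, m))

    trace = [_objective(A, W, H, beta, gamma)]
    for _ in range(max_iter):
        if gamma > 0:
            H = nnls_columns(
                np.vstack([W, sqrt_g * np.ones((1, k))]),
                np.vstack([A, zeros_row]),
            )
        else:
            H = nnls_columns(W, A)
        if beta > 0:
            W = nnls_columns(
                np.vstack([H.T, sqrt_b * eye]), np.vstack([A.T, zeros_blk])
            ).T
        else:
            W = nnls_columns(H.T, A.T).T
        obj = _objective(A, W, H, beta, gamma)
        trace.append(obj)
        prev = trace[-2]
        if abs(prev - obj) <= rel_tol * max(prev, np.finfo(float).tiny):
            break
    return W, H, trace


class SparseNMF(TransformerMixin, BaseEstimator):
    """Sparse NMF clustering of cells from expression profiles.

    Follows the scikit-learn convention: ``X`` is (n_cells, n_genes), so
    internally ``A = X.T``.  After fitting, ``components_`` holds the
    cluster representatives (k, n_genes), ``membership_`` the k x n_cells
    matrix ``H`` (W-columns normalized to unit norm), and ``labels_`` the
    hard assignment in {1..k}.

    Parameters
    ----------
    n_components : number of clusters k.
    beta, gamma : penalties; ``"auto"`` uses m/||A||_F^2 and n/||A||_F^2.
    max_iter, tol : alternation budget and relative objective-change stop.
    random_state : seed for the uniform(0, 1) * sqrt(mean(A)/k) init.
    """

    def __init__(
        self,
        n_components: int = 6,
        *,
        beta: float | str = "auto",
        gamma: float | str = "auto",
        max_iter: int = 200,
        tol: float = 1e-4,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.beta = beta
        self.gamma = gamma
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _resolve_penalties(self, A):
        beta, gamma = self.beta, self.gamma
        if isinstance(beta, str) or isinstance(gamma, str):
            b_auto, g_auto = default_regularization(A)
            if isinstance(beta, str):
                if beta != "auto":
                    raise ValueError("beta must be a float or 'auto'")
                beta = b_auto
            if isinstance(gamma, str):
                if gamma != "auto":
                    raise ValueError("gamma must be a float or 'auto'")
                gamma = g_auto
        if beta < 0 or gamma < 0:
            raise ValueError("beta and gamma must be nonnegative")
        return float(beta), float(gamma)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_cells, n_genes)")
        if (X < 0).any() or not np.isfinite(X).all():
            raise ValueError("X must be nonnegative and finite")
        A = X.T
        m, n = A.shape
        k = int(self.n_components)
        if not (1 <= k <= min(m, n)):
            raise ValueError(f"n_components={k} must be in [1, min(m, n)={min(m, n)}]")
        beta, gamma = self._resolve_penalties(A)
        rng = np.random.default_rng(self.random_state)
        W, H, trace = _anls(A, k, beta, gamma, self.max_iter, self.tol, rng)
        W, H = normalize_factors(W, H)
        self.beta_ = beta
        self.gamma_ = gamma
        self.components_ = W.T
        self.membership_ = H
        self.labels_ = hard_assign(H)
        self.objective_trace_ = trace
        self.n_iter_ = len(trace) - 1
        res = A - W @ H
        self.reconstruction_err_ = float(np.linalg.norm(res))
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).membership_.T

    def transform(self, X):
        """Membership of new cells against the fitted representatives."""
        X = np.asarray(X, dtype=float)
        W = self.components_.T
        if self.gamma_ > 0:
            k = W.shape[1]
            design = np.vstack([W, np.sqrt(self.gamma_) * np.ones((1, k))])
            rhs = np.vstack([X.T, np.zeros((1, X.shape[0]))])
        else:
            design, rhs = W, X.T
        return nnls_columns(design, rhs).T

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def sparse_nmf(
    A: np.ndarray, config: SparseNMFConfig
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Functional wrapper over :class:`SparseNMF` in genes x cells orientation.

    Returns normalized ``(W, H)`` and the objective trace.
    """
    est = SparseNMF(
        n_components=config.k,
        beta="auto" if config.beta is None else config.beta,
        gamma="auto" if config.gamma is None else config.gamma,
        max_iter=config.max_iter,
        tol=config.rel_tol,
        random_state=config.seed,
    ).fit(np.asarray(A, dtype=float).T)
    return est.components_.T, est.membership_, est.objective_trace_
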