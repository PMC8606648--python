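"""Nonnegative least squares with many right-hand sides.

Every factor update in this package reduces to problems of the form

    min_{x >= 0} || M x - b_j ||_2,    j = 1 .. q,

with either one design matrix ``M`` shared by all columns (the plain NMF
updates) or a shared design augmented per column by a weighted diagonal
block (the consensus membership update).  The solver works on the normal
equations with block principal pivoting (Kim & Park, 2011), which swaps
whole sets of active constraints at once and is much faster than
single-pivot active-set methods when many columns are solved together.
Columns on which pivoting stalls (numerically degenerate designs) fall
back to the Lawson--Hanson solver in SciPy, so the returned solution
always satisfies the KKT conditions of the constrained problem.

Rank-deficient designs are tolerated: the support solve uses ``lstsq``
when the reduced Gram matrix is singular, so the result is *a* minimizer
(not necessarily the minimum-norm one).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls as _lawson_hanson

__all__ = ["nnls_columns", "nnls_columns_penalized"]

# Kim & Park's backup counter: after this many non-improving full
# exchanges, fall back to Murty's single-variable rule (finite
# termination guarantee).
_MAX_BACKUP = 3


def _validate(M: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    M = np.asarray(M, dtype=float)
    B = np.asarray(B, dtype=float)
    if M.ndim != 2 or M.size == 0:
        raise ValueError("design matrix must be a non-empty 2-D array")
    if B.shape[0] != M.shape[0]:
        raise ValueError(
            f"rhs has {B.shape[0]} rows but design has {M.shape[0]}"
        )
    if not np.isfinite(M).all() or not np.isfinite(B).all():
        raise ValueError("non-finite entries in NNLS inputs")
    return M, B


def _bpp(G: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Block principal pivoting on the normal equations G x = F, x >= 0.

    G is (k, k) (shared) or (q, k, k) (per-column); F is (k, q).
    Returns (X, converged) where X is (k, q) and converged is a (q,)
    boolean mask; columns with ``converged == False`` need a fallback.
    """
    k, q = F.shape
    stacked = G.ndim == 3

    X = np.zeros((k, q))
    Y = -F.copy()  # Y = G X - F (dual residual)
    passive = np.zeros((k, q), dtype=bool)
    n_infeas_best = np.full(q, k + 1)
    ticket = np.full(q, _MAX_BACKUP)
    converged = np.zeros(q, dtype=bool)

    tol = 1e-12 * max(1.0, float(np.abs(F).max(initial=0.0)))
    rows = np.arange(k)

    for _ in range(10 * k + 100):
        infeas = (passive & (X < -tol)) | (~passive & (Y < -tol))
        infeas[:, converged] = False
        n_cur = infeas.sum(axis=0)
        converged |= n_cur == 0
        if converged.all():
            break
        active = ~converged

        improved = active & (n_cur < n_infeas_best)
        n_infeas_best[improved] = n_cur[improved]
        ticket[improved] = _MAX_BACKUP
        stalled = active & ~improved & (ticket == 0)
        ticket[active & ~improved & ~stalled] -= 1

        # full exchange where allowed, single (largest-index) where stalled
        full = active & ~stalled
        passive[:, full] ^= infeas[:, full]
        for j in np.flatnonzero(stalled):
            i = int(np.flatnonzero(infeas[:, j]).max())
            passive[i, j] = not passive[i, j]

        # solve the passive-set systems, grouped by support pattern
        cols = np.flatnonzero(active)
        patterns, inverse = np.unique(
            passive[:, cols], axis=1, return_inverse=True
        )
        for g in range(patterns.shape[1]):
            cj = cols[np.flatnonzero(inverse == g)]
            sup = np.flatnonzero(patterns[:, g])
            X[:, cj] = 0.0
            Y[:, cj] = -F[:, cj]
            if sup.size == 0:
                continue
            Fs = F[np.ix_(sup, cj)]
            if stacked:
                Gs = G[np.ix_(cj, sup, sup)]
                try:
                    xs = np.linalg.solve(Gs, Fs.T[..., None])[..., 0].T
                except np.linalg.LinAlgError:
                    xs = np.stack(
                        [
                            np.linalg.lstsq(Gs[i], Fs[:, i], rcond=None)[0]
                            for i in range(len(cj))
                        ],
                        axis=1,
                    )
            else:
                Gs = G[np.ix_(sup, sup)]
                try:
                    xs = np.linalg.solve(Gs, Fs)
                except np.linalg.LinAlgError:
                    xs = np.linalg.lstsq(Gs, Fs, rcond=None)[0]
            if not np.isfinite(xs).all():
                continue  # leave these columns infeasible -> fallback
            X[np.ix_(sup, cj)] = xs
            comp = np.setdiff1d(rows, sup, assume_unique=True)
            if comp.size:
                if stacked:
                    Y[np.ix_(comp, cj)] = (
                        np.einsum("cij,jc->ic", G[np.ix_(cj, comp, sup)], xs)
                        - F[np.ix_(comp, cj)]
                    )
                else:
                    Y[np.ix_(comp, cj)] = (
                        G[np.ix_(comp, sup)] @ xs - F[np.ix_(comp, cj)]
                    )
            Y[np.ix_(sup, cj)] = 0.0

    return np.maximum(X, 0.0), converged


def nnls_columns(design: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Columnwise NNLS: minimize ``||design @ x - b||`` with ``x >= 0``.

    Parameters
    ----------
    design : (p, k) array
    rhs : (p, q) or (p,) array

    Returns
    -------
    (k, q) array (or (k,) if ``rhs`` was 1-D) of nonnegative minimizers.
    """
    M, B = _validate(design, rhs)
    one_d = B.ndim == 1
    if one_d:
        B = B[:, None]
    G = M.T @ M
    F = M.T @ B
    X, ok = _bpp(G, F)
    for j in np.flatnonzero(~ok):
        X[:, j] = _lawson_hanson(M, B[:, j])[0]
    return X[:, 0] if one_d else X


def nnls_columns_penalized(
    design: np.ndarray,
    rhs: np.ndarray,
    col_penalty: np.ndarray,
    weight: float,
) -> np.ndarray:
    """Columnwise NNLS with a per-column diagonal ridge.

    For each column ``j`` solves

        min_{x >= 0} || design @ x - rhs[:, j] ||^2
                     + weight * || diag(col_penalty[:, j]) @ x ||^2,

    i.e. the stacked system with ``sqrt(weight) * diag(col_penalty[:, j])``
    appended below the design.  ``col_penalty`` is (k, q).
    """
    M, B = _validate(design, rhs)
    D = np.asarray(col_penalty, dtype=float)
    k = M.shape[1]
    if D.shape != (k, B.shape[1]):
        raise ValueError("col_penalty must be (k, q)")
    if weight < 0:
        raise ValueError("weight must be nonnegative")
    if weight == 0:
        return nnls_columns(M, B)
    q = B.shape[1]
    G0 = M.T @ M
    G = np.broadcast_to(G0, (q, k, k)).copy()
    G[:, np.arange(k), np.arange(k)] += weight * (D.T**2)
    F = M.T @ B
    X, ok = _bpp(G, F)
    root_w = np.sqrt(weight)
    for j in np.flatnonzero(~ok):
        M_aug = np.vstack([M, root_w * np.diag(D[:, j])])
        b_aug = np.concatenate([B[:, j], np.zeros(k)])
        X[:, j] = _lawson_hanson(M_aug, b_aug)[0]
    return X
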