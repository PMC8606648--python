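"""Count normalization and gene subsampling.

The clustering operates on a nonnegative genes x cells matrix ``A`` of
log-scale expression.  Raw counts are normalized per cell: each cell's
column is divided by its library size (the column total) and the result
is transformed elementwise as ``log2(x + 1)``.  No target-sum rescaling
(CPM, median library) is applied.

Gene subsampling mimics targeted spatial technologies that profile only
a few hundred genes: a uniform row subset of a stated fraction of the
genes, without replacement.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = ["normalize_expression", "sample_genes"]


def normalize_expression(
    counts: np.ndarray,
    cell_ids: Sequence[str] | None = None,
    target_sum: float | None = None,
) -> np.ndarray:
    """Library-size normalize and log2-transform a genes x cells count matrix.

    Each column is divided by its library size (the column total), rescaled
    to a common target sum, and mapped through ``log2(x + 1)``.  The default
    target is the median library size (the standard single-cell convention),
    which keeps the values on the count scale — the data-driven penalty
    defaults ``beta = m / ||A||_F^2`` and ``gamma = n / ||A||_F^2`` assume
    entries of roughly unit order and degenerate when the matrix is scaled
    down to column sums of one.  Pass ``target_sum=1.0`` for plain
    library-size fractions.

    A cell with zero total counts has no defined library size and raises
    ``ValueError`` naming the offending cell.

    Parameters
    ----------
    counts : (m, n) array of nonnegative counts, genes in rows.
    cell_ids : optional cell names used in error messages.
    target_sum : common post-scaling column sum; ``None`` means the median
        library size.

    Returns
    -------
    (m, n) array of nonnegative, finite log2 expression values.
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError("counts must be a non-empty 2-D genes x cells matrix")
    if not np.isfinite(X).all() or (X < 0).any():
        raise ValueError("counts must be finite and nonnegative")
    lib = X.sum(axis=0)
    bad = np.flatnonzero(lib <= 0)
    if bad.size:
        j = int(bad[0])
        name = cell_ids[j] if cell_ids is not None else f"column {j}"
        raise ValueError(f"cell {name!r} has zero library size")
    if target_sum is None:
        target_sum = float(np.median(lib))
    elif target_sum <= 0:
        raise ValueError("target_sum must be positive")
    return np.log2(X * (target_sum / lib) + 1.0)


def sample_genes(
    expr: np.ndarray, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform row subset of ``round(fraction * m)`` genes, without replacement.

    Returns the subset matrix and the (sorted) row indices kept, so callers
    can subset gene identifiers consistently.  ``fraction = 1.0`` returns
    the full matrix in the original gene order.  Deterministic given seed.
    """
    X = np.asarray(expr)
    if X.ndim != 2:
        raise ValueError("expression must be 2-D, genes in rows")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    m = X.shape[0]
    n_keep = int(round(fraction * m))
    if n_keep < 1:
        raise ValueError(f"fraction {fraction} keeps zero of {m} genes")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(m, size=n_keep, replace=False))
    return X[idx], idx
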