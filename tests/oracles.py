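"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own code paths: NNLS by exhaustive
active-set enumeration, and the adjusted Rand index by explicit pair
counting.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_nnls(M: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exhaustive active-set NNLS: try every support, keep the feasible best.

    Viable only for a handful of variables (2^k supports).
    """
    k = M.shape[1]
    best_x = np.zeros(k)
    best_obj = float(np.dot(b, b))
    for size in range(1, k + 1):
        for support in combinations(range(k), size):
            sup = list(support)
            x_s, *_ = np.linalg.lstsq(M[:, sup], b, rcond=None)
            if (x_s < -1e-12).any():
                continue
            x = np.zeros(k)
            x[sup] = np.maximum(x_s, 0.0)
            obj = float(np.sum((M @ x - b) ** 2))
            if obj < best_obj:
                best_obj = obj
                best_x = x
    return best_x


def pair_counting_ari(a: np.ndarray, b: np.ndarray) -> float:
    """Adjusted Rand index from explicit agreement counts over all pairs."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    both = same_a = same_b = 0
    for i, j in combinations(range(n), 2):
        sa = a[i] == a[j]
        sb = b[i] == b[j]
        both += sa and sb
        same_a += sa
        same_b += sb
    n_pairs = n * (n - 1) // 2
    expected = same_a * same_b / n_pairs
    max_index = 0.5 * (same_a + same_b)
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)
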