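"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths (and the libraries) they are
checking: Ward clustering is re-derived from raw within-cluster sums of
squares, eigenvalues come from a plain Jacobi rotation solver, and OLS from
the textbook closed form.
"""

from __future__ import annotations

import numpy as np


def brute_force_ward(x: np.ndarray):
    """Agglomerate by direct minimum-variance search.

    At every step the merge cost of each cluster pair is computed from the
    raw points as the increase in within-cluster sum of squares; the pair
    with the smallest cost merges (ties toward the smallest cluster-id
    pair).  Returns (merge member-sets, Euclidean-scale heights).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]

    def sse(idx: list[int]) -> float:
        pts = x[idx]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    next_id = n
    merges: list[tuple[frozenset, frozenset, float]] = []
    while len(clusters) > 1:
        best = None
        for i in sorted(clusters):
            for j in sorted(clusters):
                if j <= i:
                    continue
                cost = sse(clusters[i] + clusters[j]) - sse(clusters[i]) - sse(clusters[j])
                if best is None or cost < best[0] - 1e-12 * max(1.0, abs(best[0])):
                    best = (cost, i, j)
        cost, i, j = best
        merges.append(
            (frozenset(clusters[i]), frozenset(clusters[j]), float(np.sqrt(2.0 * cost)))
        )
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return merges


def jacobi_eigenvalues(a: np.ndarray, tol: float = 1e-14, max_sweeps: int = 100):
    """Eigenvalues of a symmetric matrix by classical Jacobi rotations."""
    a = np.array(a, dtype=float)
    p = a.shape[0]
    for _ in range(max_sweeps):
        off = np.sqrt(abs((a**2).sum() - (np.diag(a) ** 2).sum()))
        if off < tol:
            break
        for i in range(p - 1):
            for j in range(i + 1, p):
                if abs(a[i, j]) < tol / (p * p):
                    continue
                # zero a[i, j]: tan(2 theta) = 2 a_ij / (a_ii - a_jj)
                theta = 0.5 * np.arctan2(2.0 * a[i, j], a[i, i] - a[j, j])
                c, s = np.cos(theta), np.sin(theta)
                rot = np.eye(p)
                rot[i, i] = rot[j, j] = c
                rot[i, j] = -s
                rot[j, i] = s
                a = rot.T @ a @ rot
    return np.sort(np.diag(a))[::-1]


def ols_closed_form(x: np.ndarray, y: np.ndarray):
    """Textbook simple-regression slope/intercept/Pearson r."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    sxx = (x**2).sum() - x.sum() ** 2 / n
    syy = (y**2).sum() - y.sum() ** 2 / n
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    r = sxy / np.sqrt(sxx * syy)
    return slope, intercept, r
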