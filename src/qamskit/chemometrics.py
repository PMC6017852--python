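"""Batch classification: standardization, Ward HCA, correlation-matrix PCA,
and radar-plot group summaries.

The clustering and PCA cores are implemented in-repo (Lance-Williams
recurrence, symmetric eigendecomposition of the correlation matrix) so that
they can be checked against brute-force oracles in the test suite.

A note on preprocessing: correlation-matrix PCA standardizes implicitly.
For hierarchical clustering, :func:`hca_ward` operates on whatever matrix it
is given; pass the output of :func:`standardize` to cluster z-scores, or the
raw content matrix to cluster absolute contents.  On the packaged 20-batch
reference table only the *raw* contents reproduce the published three-group
partition (z-scoring moves the last two samples across a group boundary
under every Ward variant), so the reproduction pipeline defaults to raw
contents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BatchContentMatrix",
    "ClusteringResult",
    "PCAResult",
    "standardize",
    "hca_ward",
    "cut_tree",
    "pca",
    "radar_table",
]


@dataclass
class BatchContentMatrix:
    """Samples x analytes concentration table (ug/mL) with a method tag."""

    samples: list[str]
    analytes: list[str]
    values: np.ndarray
    method: str = "ESM"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.analytes)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.analytes)} analytes"
            )
        if np.any(~np.isfinite(self.values)):
            raise ValueError("content matrix contains missing/non-finite cells")
        if np.any(self.values < 0):
            raise ValueError("contents must be >= 0")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, method: str = "ESM") -> "BatchContentMatrix":
        return cls(
            samples=[str(s) for s in df.index],
            analytes=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            method=method,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(), index=list(self.samples), columns=list(self.analytes)
        )

    def row(self, sample: str) -> dict[str, float]:
        i = self.samples.index(sample)
        return {a: float(v) for a, v in zip(self.analytes, self.values[i])}

    def column(self, analyte: str) -> np.ndarray:
        return self.values[:, self.analytes.index(analyte)].copy()


def _as_array(matrix) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(matrix, BatchContentMatrix):
        return matrix.values, list(matrix.samples), list(matrix.analytes)
    if isinstance(matrix, pd.DataFrame):
        return (
            matrix.to_numpy(dtype=float),
            [str(i) for i in matrix.index],
            [str(c) for c in matrix.columns],
        )
    x = np.asarray(matrix, dtype=float)
    return x, [f"row{i}" for i in range(x.shape[0])], [f"col{j}" for j in range(x.shape[1])]


def standardize(matrix):
    """Column-wise z-scores (mean 0, sample SD 1, n-1 denominator).

    Returns a DataFrame for labelled inputs and an ndarray for plain arrays.
    """
    x, samples, analytes = _as_array(matrix)
    sd = x.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"column {analytes[j]} is constant; cannot standardize")
    z = (x - x.mean(axis=0)) / sd
    if isinstance(matrix, np.ndarray):
        return z
    return pd.DataFrame(z, index=samples, columns=analytes)


@dataclass
class ClusteringResult:
    """Agglomeration record: cluster ids 0..n-1 are singletons, merge ``i``
    creates cluster ``n+i``.  Heights are Euclidean-scale (Ward.D2) or raw
    Lance-Williams dissimilarities (ward.d)."""

    n: int
    merges: list[tuple[int, int, float, int]]  # (left, right, height, new size)
    linkage: str = "ward.d2"
    distance: str = "euclidean"
    sample_ids: list[str] = field(default_factory=list)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def members(self) -> dict[int, list[int]]:
        out = {i: [i] for i in range(self.n)}
        for k, (a, b, _, _) in enumerate(self.merges):
            out[self.n + k] = out[a] + out[b]
        return out

    def to_newick(self) -> str:
        labels = self.sample_ids or [str(i) for i in range(self.n)]
        members = self.members()
        height = {i: 0.0 for i in range(self.n)}
        node = {i: labels[i] for i in range(self.n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            nid = self.n + k
            height[nid] = h
            la = max(h - height[a], 0.0)
            lb = max(h - height[b], 0.0)
            node[nid] = f"({node[a]}:{la:g},{node[b]}:{lb:g})"
        return node[self.n + len(self.merges) - 1] + ";"


def hca_ward(matrix, variant: str = "ward.d2") -> ClusteringResult:
    """Agglomerative Ward clustering on Euclidean distances.

    ``variant='ward.d2'`` (default) runs the Lance-Williams recurrence on
    squared Euclidean distances and reports Euclidean-scale merge heights
    (the classical minimum-variance criterion).  ``variant='ward.d'`` applies
    the same recurrence to unsquared distances.  Ties are broken toward the
    lexicographically smallest cluster-id pair, so the merge sequence is
    deterministic and sample-order invariant up to relabelling.
    """
    x, samples, _ = _as_array(matrix)
    n = x.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 samples")
    if variant not in ("ward.d2", "ward.d"):
        raise ValueError(f"unknown Ward variant: {variant!r}")

    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    dis = d**2 if variant == "ward.d2" else d

    # dissimilarity store keyed by active cluster ids
    dd: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dd[(i, j)] = float(dis[i, j])
    size = {i: 1 for i in range(n)}
    active = set(range(n))

    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        ordered = sorted(active)
        for ai, i in enumerate(ordered):
            for j in ordered[ai + 1 :]:
                v = dd[(i, j)]
                if best is None or v < best[0] - 1e-15 * max(1.0, abs(best[0])):
                    best = (v, i, j)
        cost, i, j = best
        ni, nj = size[i], size[j]
        for k in active:
            if k in (i, j):
                continue
            nk = size[k]
            dik = dd[(min(i, k), max(i, k))]
            djk = dd[(min(j, k), max(j, k))]
            dd[(k, next_id)] = ((ni + nk) * dik + (nj + nk) * djk - nk * cost) / (
                ni + nj + nk
            )
        active -= {i, j}
        active.add(next_id)
        size[next_id] = ni + nj
        height = float(np.sqrt(cost)) if variant == "ward.d2" else float(cost)
        merges.append((i, j, height, ni + nj))
        next_id += 1

    return ClusteringResult(
        n=n, merges=merges, linkage=variant, distance="euclidean", sample_ids=samples
    )


def cut_tree(result: ClusteringResult, k: int) -> np.ndarray:
    """Labels 1..k obtained by undoing the last k-1 merges.

    Clusters are numbered by the index of their first (smallest-index)
    member, so the labelling is stable across equivalent merge orders.
    """
    n = result.n
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    members = {i: [i] for i in range(n)}
    active = set(range(n))
    for step, (a, b, _, _) in enumerate(result.merges[: n - k]):
        nid = n + step
        members[nid] = members[a] + members[b]
        active -= {a, b}
        active.add(nid)
    labels = np.empty(n, dtype=int)
    for rank, cid in enumerate(sorted(active, key=lambda c: min(members[c])), start=1):
        labels[np.array(members[cid])] = rank
    return labels


@dataclass
class PCAResult:
    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    cumulative_pct: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    variable_ids: list[str] = field(default_factory=list)

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.variable_ids, columns=cols)


def pca(matrix) -> PCAResult:
    """Correlation-matrix PCA (eigendecomposition of the Pearson correlation
    of the columns; equivalently covariance of z-scores, n-1 denominator).

    Explained variance per component is eigenvalue / n_variables * 100, so
    the percentages always sum to 100.  Sign convention: the largest-
    magnitude entry of each loading vector is made positive.
    """
    x, samples, variables = _as_array(matrix)
    n, p = x.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs at least 2 samples and 2 variables")
    sd = x.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"column {variables[j]} is constant; cannot run PCA")
    z = (x - x.mean(axis=0)) / sd
    corr = z.T @ z / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for j in range(p):
        i = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    explained = eigval / p * 100.0
    return PCAResult(
        eigenvalues=eigval,
        explained_pct=explained,
        cumulative_pct=np.cumsum(explained),
        scores=z @ eigvec,
        loadings=eigvec,
        sample_ids=samples,
        variable_ids=variables,
    )


def radar_table(matrix, labels: Sequence[int]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean contents plus per-sample profiles scaled to column max.

    Returns ``(group_means, normalized_profiles)``; both are CSV-ready.
    """
    x, samples, analytes = _as_array(matrix)
    labels = np.asarray(labels)
    if labels.shape != (x.shape[0],):
        raise ValueError("labels must assign exactly one group per sample")
    groups = sorted(set(int(g) for g in labels))
    means = {}
    for g in groups:
        mask = labels == g
        if not mask.any():
            raise ValueError(f"group {g} is empty")
        means[g] = x[mask].mean(axis=0)
    group_means = pd.DataFrame.from_dict(means, orient="index", columns=analytes)
    group_means.index.name = "group"
    col_max = x.max(axis=0)
    if np.any(col_max == 0):
        raise ValueError("cannot normalize a column whose maximum is 0")
    normalized = pd.DataFrame(x / col_max, index=samples, columns=analytes)
    return group_means, normalized
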