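"""Partitioning the gene-relativity graph over a threshold grid.

The relativity matrix R is binarized at a threshold sigma >= 0.5 (edge
iff R[i, j] >= sigma); the connected components of the resulting graph
are the initial clusters. Sweeping sigma over a grid (default 0.50,
0.51, ..., 0.80) yields a nested family of partitions — raising sigma
only removes edges, so components only split. The working partition is
selected as the sigma maximizing the Silhouette index of the *initial*
(pre-refinement) partitions, ties broken toward the smallest sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components as _cc

from .consensus import RelativityMatrix
from .validity import silhouette

__all__ = [
    "Partition",
    "ThresholdSweep",
    "default_sigma_grid",
    "binarize",
    "connected_components",
    "sweep",
    "select_threshold",
]


@dataclass
class Partition:
    """Cluster assignment: contiguous labels 1..K in first-appearance order."""

    labels: np.ndarray
    source_threshold: float | None = None

    def __post_init__(self) -> None:
        self.labels = canonical_labels(self.labels)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    @property
    def n_genes(self) -> int:
        return self.labels.size

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels)[1:]

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster)


@dataclass
class ThresholdSweep:
    """Per-threshold initial partitions and their Silhouette values."""

    grid: np.ndarray
    partitions: list[Partition]
    silhouettes: np.ndarray = field(default=None)


def canonical_labels(labels) -> np.ndarray:
    """Renumber arbitrary labels to 1..K in order of first appearance."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    renum: dict = {}
    out = np.empty(labels.size, dtype=int)
    for i, lab in enumerate(labels.tolist()):
        out[i] = renum.setdefault(lab, len(renum) + 1)
    return out


def default_sigma_grid() -> np.ndarray:
    """The 31-value grid 0.50, 0.51, ..., 0.80."""
    return np.round(np.arange(50, 81) / 100.0, 2)


def binarize(R: RelativityMatrix, sigma: float) -> np.ndarray:
    """Boolean adjacency: edge iff relativity >= sigma (diagonal excluded)."""
    if sigma < 0.5:
        raise ValueError(f"relativity threshold must be >= 0.5, got {sigma}")
    adj = R.values >= sigma
    np.fill_diagonal(adj, False)
    return adj


def connected_components(adjacency: np.ndarray) -> Partition:
    """Partition an undirected binary graph into its connected components.

    Components are numbered 1..K by the first gene (input order) they
    contain, so output labels are stable across equivalent edge orderings.
    """
    adjacency = np.asarray(adjacency, dtype=bool)
    n_comp, raw = _cc(csr_matrix(adjacency), directed=False)
    return Partition(raw)


def sweep(R: RelativityMatrix, grid=None) -> ThresholdSweep:
    """One initial partition per threshold on the grid."""
    grid = default_sigma_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("threshold grid must be strictly increasing")
    partitions = []
    for sigma in grid:
        part = connected_components(binarize(R, float(sigma)))
        part.source_threshold = float(sigma)
        partitions.append(part)
    return ThresholdSweep(grid=grid, partitions=partitions)


def select_threshold(
    sw: ThresholdSweep, data: np.ndarray, dissimilarity: str = "euclidean"
) -> tuple[float, Partition]:
    """Pick sigma* = argmax Silhouette over the sweep's initial partitions.

    Trivial partitions (one cluster, or every gene its own cluster) have
    no meaningful Silhouette and are skipped. Ties go to the smallest
    sigma. Computed Silhouette values are stored on the sweep.
    """
    n = sw.partitions[0].n_genes
    scores = np.full(sw.grid.size, np.nan)
    for i, part in enumerate(sw.partitions):
        k = part.n_clusters
        if k < 2 or k >= n:
            continue
        scores[i] = silhouette(data, part.labels, dissimilarity)
    sw.silhouettes = scores
    if np.all(np.isnan(scores)):
        raise ValueError(
            "every threshold produced a trivial partition (K = 1 or K = n); "
            "widen the window range or inspect the relativity matrix"
        )
    best = int(np.nanargmax(scores))  # first occurrence => smallest sigma on ties
    return float(sw.grid[best]), sw.partitions[best]
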