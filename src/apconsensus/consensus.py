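"""Consensus (evidence-accumulation) aggregation of per-window clusterings.

Each window's clustering is encoded as a binary co-cluster adjacency
matrix ("vote"). Votes at one window size are averaged entrywise into a
per-size consensus matrix, and the per-size matrices are averaged again —
with equal weight per window size, regardless of how many windows each
size contributes — into the gene-relativity matrix R. Entry R[i, j] is
the empirical probability that genes i and j land in the same cluster,
and R is the weighted-edge matrix of the gene-relativity graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RelativityMatrix",
    "adjacency_from_labels",
    "consensus_for_size",
    "aggregate",
    "VoteAccumulator",
]


@dataclass
class RelativityMatrix:
    """Symmetric matrix of co-cluster probabilities with its vote count."""

    values: np.ndarray
    vote_count: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"relativity matrix must be square, got {v.shape}")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0):
            raise ValueError("relativity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("relativity entries must lie in [0, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("relativity diagonal must be 1")
        np.clip(v, 0.0, 1.0, out=v)
        np.fill_diagonal(v, 1.0)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


def adjacency_from_labels(labels: np.ndarray) -> np.ndarray:
    """Binary co-cluster adjacency: 1 where two points share a label."""
    labels = np.asarray(labels)
    if labels.ndim != 1:
        raise ValueError("labels must be a 1-D vector")
    return (labels[:, None] == labels[None, :]).astype(float)


def consensus_for_size(adjacencies: list[np.ndarray]) -> RelativityMatrix:
    """Entrywise mean of one window size's votes."""
    if not adjacencies:
        raise ValueError("need at least one adjacency matrix")
    stack = np.asarray(adjacencies, dtype=float)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("adjacency matrices must be square and uniform in size")
    return RelativityMatrix(stack.mean(axis=0), vote_count=stack.shape[0])


def aggregate(per_size: list[RelativityMatrix]) -> RelativityMatrix:
    """Unweighted mean over window sizes (each size counts once)."""
    if not per_size:
        raise ValueError("need at least one consensus matrix")
    n = per_size[0].n_genes
    if any(m.n_genes != n for m in per_size):
        raise ValueError("consensus matrices differ in dimension")
    mean = np.mean([m.values for m in per_size], axis=0)
    return RelativityMatrix(mean, vote_count=sum(m.vote_count for m in per_size))


class VoteAccumulator:
    """Running-sum accumulator: O(n^2) memory however many votes arrive.

    Votes are binned by window size; ``relativity()`` performs the two-stage
    average (mean within size, then unweighted mean across sizes).
    """

    def __init__(self, n_genes: int) -> None:
        self.n_genes = n_genes
        self._sums: dict[int, np.ndarray] = {}
        self._counts: dict[int, int] = {}

    def add(self, window_size: int, labels: np.ndarray) -> None:
        adj = adjacency_from_labels(labels)
        if adj.shape[0] != self.n_genes:
            raise ValueError("label vector length does not match gene count")
        if window_size not in self._sums:
            self._sums[window_size] = np.zeros((self.n_genes, self.n_genes))
            self._counts[window_size] = 0
        self._sums[window_size] += adj
        self._counts[window_size] += 1

    @property
    def vote_count(self) -> int:
        return sum(self._counts.values())

    def relativity(self) -> RelativityMatrix:
        if not self._sums:
            raise ValueError("no votes accumulated")
        per_size = [
            RelativityMatrix(self._sums[w] / self._counts[w], self._counts[w])
            for w in sorted(self._sums)
        ]
        return aggregate(per_size)
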