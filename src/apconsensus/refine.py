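"""Refinement of an initial partition by merging minor sub-clusters.

Thresholding the relativity graph tends to strand small connected
components ("sub-clusters": fewer than phi genes) whose linking edges
fell just below the threshold. Refinement merges them back:

* Rule 1 (singletons): find the gene with the highest relativity to the
  lone member. Below 0.5 the singleton survives; otherwise it merges into
  that gene's cluster — if that cluster is itself a sub-cluster the two
  merge and the combined size is re-classified.
* Rule 2 (multi-gene sub-clusters): compute the sub-cluster's mean
  expression profile and the mean profile of every major cluster; merge
  into the major cluster with the highest Pearson correlation, unless
  even the best correlation is negative, in which case the sub-cluster
  survives.

Rules are applied repeatedly — smallest sub-cluster first, ties by
cluster index — until no mergeable sub-cluster remains or the iteration
cap is hit. Survivors under Rule 1.1 / 2.1 are terminal and do not
re-enter the queue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .consensus import RelativityMatrix
from .graph import Partition

logger = logging.getLogger(__name__)

__all__ = ["ClusterClassification", "classify", "default_phi", "refine"]

SINGLETON_RELATIVITY_CUTOFF = 0.5  # Rule 1.1
MEAN_PROFILE_CORRELATION_CUTOFF = 0.0  # Rule 2.1
DEFAULT_MAX_ITERATIONS = 500


@dataclass
class ClusterClassification:
    """Size-based split of cluster indices into major and sub-clusters."""

    phi: int
    major: list[int]
    sub: list[int]


def default_phi(n_genes: int) -> int:
    """Default minor-cluster threshold: max(2, 1% of the gene count)."""
    return max(2, int(np.ceil(0.01 * n_genes)))


def classify(partition: Partition, phi: int) -> ClusterClassification:
    """Split clusters into major (size >= phi) and sub (size < phi)."""
    if phi < 1:
        raise ValueError(f"phi must be >= 1, got {phi}")
    if phi >= partition.n_genes:
        raise ValueError(
            f"phi={phi} >= n={partition.n_genes}: every cluster would be minor"
        )
    sizes = partition.sizes()
    major = [c + 1 for c in range(sizes.size) if sizes[c] >= phi]
    sub = [c + 1 for c in range(sizes.size) if sizes[c] < phi]
    return ClusterClassification(phi=phi, major=major, sub=sub)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0:
        return 0.0
    return float(xc @ yc / denom)


class _Refiner:
    """Mutable cluster sets during one refinement run."""

    def __init__(self, partition: Partition, R: RelativityMatrix,
                 values: np.ndarray, phi: int) -> None:
        self.R = R.values
        self.values = np.asarray(values, dtype=float)
        self.phi = phi
        self.clusters: list[set[int]] = [
            set(np.flatnonzero(partition.labels == c + 1).tolist())
            for c in range(partition.n_clusters)
        ]
        self.terminal: set[int] = set()  # survivors under Rules 1.1 / 2.1

    def _sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def _majors(self) -> list[int]:
        return [i for i, c in enumerate(self.clusters) if len(c) >= self.phi]

    def _pending_subs(self) -> list[int]:
        """Sub-clusters still in play, smallest first, ties by index."""
        subs = [
            i for i, c in enumerate(self.clusters)
            if 0 < len(c) < self.phi and i not in self.terminal
        ]
        return sorted(subs, key=lambda i: (len(self.clusters[i]), i))

    def _merge(self, src: int, dst: int) -> None:
        self.clusters[dst] |= self.clusters[src]
        self.clusters[src] = set()
        self.terminal.discard(dst)  # combined cluster gets re-examined

    def _cluster_of_gene(self, g: int) -> int:
        for i, c in enumerate(self.clusters):
            if g in c:
                return i
        raise RuntimeError(f"gene {g} lost during refinement")

    def step(self, q: int) -> bool:
        """Apply Rule 1 or 2 to sub-cluster q; True if a merge happened."""
        members = self.clusters[q]
        if len(members) == 1:
            g = next(iter(members))
            rel = self.R[g].copy()
            rel[g] = -np.inf
            h_gene = int(np.argmax(rel))
            if rel[h_gene] < SINGLETON_RELATIVITY_CUTOFF:  # Rule 1.1
                self.terminal.add(q)
                return False
            h = self._cluster_of_gene(h_gene)
            self._merge(q, h)  # Rules 1.2 / 1.3; type rechecked next pass
            return True
        majors = [m for m in self._majors() if m != q]
        if not majors:  # Rule 2 presupposes a major cluster
            self.terminal.add(q)
            return False
        q_mean = self.values[sorted(members)].mean(axis=0)
        corrs = [
            _pearson(q_mean, self.values[sorted(self.clusters[m])].mean(axis=0))
            for m in majors
        ]
        best = int(np.argmax(corrs))
        if corrs[best] < MEAN_PROFILE_CORRELATION_CUTOFF:  # Rule 2.1
            self.terminal.add(q)
            return False
        self._merge(q, majors[best])  # Rule 2.2
        return True

    def labels(self) -> np.ndarray:
        n = self.values.shape[0]
        out = np.empty(n, dtype=int)
        for i, c in enumerate(self.clusters):
            for g in c:
                out[g] = i
        return out


def refine(
    partition: Partition,
    R: RelativityMatrix,
    values: np.ndarray,
    phi: int | None = None,
    max_iterations: int = DEFAULT_MAX_ITERATIONS,
) -> Partition:
    """Merge sub-clusters into majors until a fixed point (or the cap).

    Parameters
    ----------
    partition : Partition
        Initial clustering (connected components at the selected sigma).
    R : RelativityMatrix
        Gene-relativity matrix; Rule 1 reads singleton relativities here.
    values : ndarray of shape (n, p)
        Working expression matrix (interpolated grid when interpolation is
        on); Rule 2 correlates mean profiles on it.
    phi : int, optional
        Minor-cluster size threshold; default max(2, ceil(0.01 n)).
    max_iterations : int
        Safety cap on merge iterations (each productive iteration removes
        at least one cluster, so the cap is rarely binding).
    """
    if phi is None:
        phi = default_phi(partition.n_genes)
    ref = _Refiner(partition, R, values, phi)

    iterations = 0
    while iterations < max_iterations:
        pending = ref._pending_subs()
        if not pending:
            break
        iterations += 1
        if not ref.step(pending[0]):
            continue
    else:
        if ref._pending_subs():
            logger.warning(
                "refinement hit the %d-iteration cap with sub-clusters remaining",
                max_iterations,
            )
    return Partition(ref.labels(), source_threshold=partition.source_threshold)
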