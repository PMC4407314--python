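"""Cluster validity indices.

External indices compare a clustering U against a reference labeling V
through the pair-counting confusion (TP/FP/FN/TN over all gene pairs):
the adjusted Rand index, sensitivity TP/(TP+FN), specificity TP/(TP+FP)
(pair precision — note this is the pair-counting usage common in the
gene-expression clustering literature, not 1 - FPR), the Jaccard index
TP/(TP+FN+FP) and the Minkowski measure sqrt((FP+FN)/(TP+FN)).

Internal indices judge a clustering from the data alone: the Silhouette
index (cohesion vs. nearest-other-cluster separation, in [-1, 1]), Dunn's
index (min inter-cluster separation over max cluster diameter) and the
Davies-Bouldin index (mean worst-pair dispersion-to-separation ratio).
Dissimilarity is Euclidean by default, with a correlation mode
d = 1 - Pearson matching the pipeline's similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, sqrt

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PairConfusion",
    "ValidityReport",
    "contingency",
    "adjusted_rand",
    "rand_index",
    "pair_confusion",
    "minkowski_measure",
    "silhouette",
    "dunn",
    "davies_bouldin",
    "external_report",
    "internal_report",
]


@dataclass(frozen=True)
class PairConfusion:
    """Pair counts over all C(n, 2) unordered gene pairs."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ValidityReport:
    ari: float | None = None
    rand: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    jaccard: float | None = None
    minkowski: float | None = None
    silhouette: float | None = None
    dunn: float | None = None
    dbi: float | None = None

    def as_dict(self) -> dict[str, float]:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _as_codes(labels) -> np.ndarray:
    labels = np.asarray(labels)
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def contingency(u, v) -> np.ndarray:
    """Cross-tabulation n_ij of cluster memberships of U against classes of V."""
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError(f"label vectors differ in length: {u.size} vs {v.size}")
    ui = _as_codes(u)
    vi = _as_codes(v)
    table = np.zeros((ui.max() + 1, vi.max() + 1), dtype=np.int64)
    np.add.at(table, (ui, vi), 1)
    return table


def _pair_counts(table: np.ndarray) -> tuple[int, int, int, int]:
    n = int(table.sum())
    tp = int(sum(comb(int(x), 2) for x in table.ravel()))
    same_u = int(sum(comb(int(x), 2) for x in table.sum(axis=1)))
    same_v = int(sum(comb(int(x), 2) for x in table.sum(axis=0)))
    fp = same_u - tp
    fn = same_v - tp
    tn = comb(n, 2) - tp - fp - fn
    return tp, fp, fn, tn


def pair_confusion(u, v) -> PairConfusion:
    """TP/FP/FN/TN pair counts, computed through the contingency table."""
    tp, fp, fn, tn = _pair_counts(contingency(u, v))
    return PairConfusion(tp, fp, fn, tn)


def adjusted_rand(u, v) -> float:
    """Chance-corrected pair agreement between two labelings; 1 = identical."""
    table = contingency(u, v)
    n = int(table.sum())
    if n < 2:
        raise ValueError("need at least 2 objects")
    sum_ij = sum(comb(int(x), 2) for x in table.ravel())
    sum_i = sum(comb(int(x), 2) for x in table.sum(axis=1))
    sum_j = sum(comb(int(x), 2) for x in table.sum(axis=0))
    expected = sum_i * sum_j / comb(n, 2)
    max_index = (sum_i + sum_j) / 2
    if max_index == expected:
        # both partitions trivial (all-one-cluster or all-singletons)
        if np.array_equal(_as_codes(u), _as_codes(v)):
            return 1.0
        raise ValueError("ARI undefined: both partitions are trivial and differ")
    return float((sum_ij - expected) / (max_index - expected))


def rand_index(u, v) -> float:
    pc = pair_confusion(u, v)
    return (pc.tp + pc.tn) / pc.total


def minkowski_measure(pc: PairConfusion) -> float:
    """sqrt((FP + FN) / (TP + FN)); 0 for perfect agreement."""
    if pc.tp + pc.fn == 0:
        raise ValueError(
            "Minkowski measure undefined: reference has no co-clustered pair"
        )
    return sqrt((pc.fp + pc.fn) / (pc.tp + pc.fn))


def _dissimilarity(data: np.ndarray, mode: str) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if mode == "euclidean":
        return squareform(pdist(data))
    if mode == "correlation":
        d = squareform(pdist(data, metric="correlation"))  # 1 - Pearson
        np.fill_diagonal(d, 0.0)
        return d
    raise ValueError(f"unknown dissimilarity mode {mode!r}")


def silhouette(data, labels, dissimilarity: str = "euclidean") -> float:
    """Mean Silhouette width s(i) = (b(i) - a(i)) / max(a(i), b(i)).

    a(i) is the mean dissimilarity of i to its own cluster's other members;
    b(i) the smallest mean dissimilarity to any other cluster. Members of
    singleton clusters score 0 by convention.
    """
    labels = _as_codes(labels)
    k = labels.max() + 1
    if k < 2:
        raise ValueError("Silhouette undefined for a single cluster")
    D = _dissimilarity(data, dissimilarity)
    n = D.shape[0]
    sizes = np.bincount(labels, minlength=k)
    if not (sizes >= 2).any():
        return 0.0  # all singletons: every s(i) is 0 by convention
    # mean dissimilarity of each point to each cluster
    sums = np.zeros((n, k))
    for c in range(k):
        sums[:, c] = D[:, labels == c].sum(axis=1)
    own = labels
    s = np.zeros(n)
    for i in range(n):
        c = own[i]
        if sizes[c] == 1:
            continue  # singleton convention s(i) = 0
        a = sums[i, c] / (sizes[c] - 1)
        others = [sums[i, o] / sizes[o] for o in range(k) if o != c]
        b = min(others)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def dunn(
    data, labels, dissimilarity: str = "euclidean", linkage: str = "single"
) -> float:
    """Dunn's index: min inter-cluster distance over max cluster diameter."""
    labels = _as_codes(labels)
    k = labels.max() + 1
    if k < 2:
        raise ValueError("Dunn index undefined for a single cluster")
    D = _dissimilarity(data, dissimilarity)
    members = [np.flatnonzero(labels == c) for c in range(k)]
    diam = max(
        (D[np.ix_(m, m)].max() if m.size > 1 else 0.0) for m in members
    )
    if linkage == "single":
        sep = min(
            D[np.ix_(members[i], members[j])].min()
            for i in range(k)
            for j in range(i + 1, k)
        )
    elif linkage == "centroid":
        cents = np.asarray(
            [np.asarray(data, dtype=float)[m].mean(axis=0) for m in members]
        )
        cd = squareform(pdist(cents))
        iu = np.triu_indices(k, 1)
        sep = cd[iu].min()
    else:
        raise ValueError(f"unknown linkage {linkage!r}")
    if diam == 0:
        if sep == 0:
            raise ValueError("Dunn index undefined: zero diameter and separation")
        return float("inf")
    return float(sep / diam)


def davies_bouldin(data, labels) -> float:
    """Davies-Bouldin index (Euclidean, centroid dispersion); small = compact."""
    data = np.asarray(data, dtype=float)
    labels = _as_codes(labels)
    k = labels.max() + 1
    if k < 2:
        raise ValueError("Davies-Bouldin index undefined for a single cluster")
    members = [np.flatnonzero(labels == c) for c in range(k)]
    cents = np.asarray([data[m].mean(axis=0) for m in members])
    disp = np.asarray(
        [np.linalg.norm(data[m] - cents[c], axis=1).mean() for c, m in enumerate(members)]
    )
    sep = squareform(pdist(cents))
    if np.any(sep[np.triu_indices(k, 1)] == 0):
        raise ValueError("Davies-Bouldin undefined: coincident cluster centroids")
    ratios = (disp[:, None] + disp[None, :]) / np.where(sep == 0, np.inf, sep)
    np.fill_diagonal(ratios, -np.inf)
    return float(ratios.max(axis=1).mean())


def external_report(u, v) -> ValidityReport:
    """All external indices of clustering u against reference labeling v."""
    pc = pair_confusion(u, v)
    return ValidityReport(
        ari=adjusted_rand(u, v),
        rand=(pc.tp + pc.tn) / pc.total,
        sensitivity=pc.tp / (pc.tp + pc.fn) if pc.tp + pc.fn else float("nan"),
        specificity=pc.tp / (pc.tp + pc.fp) if pc.tp + pc.fp else float("nan"),
        jaccard=pc.tp / (pc.tp + pc.fn + pc.fp) if pc.tp + pc.fn + pc.fp else float("nan"),
        minkowski=minkowski_measure(pc) if pc.tp + pc.fn else float("nan"),
    )


def internal_report(data, labels, dissimilarity: str = "euclidean") -> ValidityReport:
    """Silhouette, Dunn and Davies-Bouldin indices of a clustering."""
    return ValidityReport(
        silhouette=silhouette(data, labels, dissimilarity),
        dunn=dunn(data, labels, dissimilarity),
        dbi=davies_bouldin(data, labels),
    )
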