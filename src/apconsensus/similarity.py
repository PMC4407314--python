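"""Feature windows over the time grid and per-window Pearson similarity.

Two window modes are supported. *Sliding* mode enumerates every contiguous
block of w time points (p - w + 1 windows on a p-point grid) and is the
default. *Subset* ("extended") mode draws random w-point subsets of the
grid instead, useful for very short series (tau < 10) where the sliding
windows alone contribute too few consensus votes.

Gene similarity inside a window is the Pearson correlation of the two
profiles restricted to the window's time points. A profile that is flat
over the window has undefined correlation; by convention it contributes 0
(no co-expression evidence), while the diagonal is always 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np

__all__ = [
    "FeatureWindow",
    "recommended_window_range",
    "sliding_windows",
    "subset_windows",
    "window_correlation",
]


@dataclass(frozen=True)
class FeatureWindow:
    """An ordered set of time-point indices used as one feature vector."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(idx) < 2:
            raise ValueError("a feature window needs at least 2 time points")
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("window indices must be strictly increasing")
        if idx[0] < 0:
            raise ValueError("window indices must be non-negative")

    @property
    def size(self) -> int:
        return len(self.indices)


def recommended_window_range(p: int) -> tuple[int, int]:
    """Default window-size range [floor(p/2), floor(3p/4)] for a p-point grid.

    ``p`` is the working grid size: 2*tau - 1 after interpolation of tau
    observed points, or tau itself when interpolation is off. The range
    trades off feature informativeness (larger w) against the number of
    consensus votes (smaller w): e.g. p=33 -> (16, 24), p=20 -> (10, 15).
    """
    if p < 4:
        raise ValueError(f"need at least 4 time points, got {p}")
    return p // 2, (3 * p) // 4


def sliding_windows(p: int, w: int) -> list[FeatureWindow]:
    """All p - w + 1 contiguous windows of size w, in left-to-right order."""
    if w < 2:
        raise ValueError(f"window size must be >= 2, got {w}")
    if w > p:
        raise ValueError(f"window size {w} exceeds {p} time points")
    return [FeatureWindow(tuple(range(s, s + w))) for s in range(p - w + 1)]


def subset_windows(
    tau: int, w: int, max_subsets: int = 200, seed: int | None = None
) -> list[FeatureWindow]:
    """Distinct random w-point subsets of a tau-point grid (extended mode).

    Returns all C(tau, w) subsets when that count is within ``max_subsets``;
    otherwise samples ``max_subsets`` distinct subsets uniformly without
    replacement, reproducibly for a fixed ``seed``.
    """
    if max_subsets < 1:
        raise ValueError(f"max_subsets must be >= 1, got {max_subsets}")
    if w < 2:
        raise ValueError(f"window size must be >= 2, got {w}")
    if w > tau:
        raise ValueError(f"window size {w} exceeds {tau} time points")
    total = comb(tau, w)
    if total <= max_subsets:
        return [FeatureWindow(c) for c in itertools.combinations(range(tau), w)]
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < max_subsets:
        chosen.add(tuple(sorted(rng.choice(tau, size=w, replace=False).tolist())))
    return [FeatureWindow(c) for c in sorted(chosen)]


def window_correlation(values: np.ndarray, window: FeatureWindow) -> np.ndarray:
    """Gene x gene Pearson correlation matrix restricted to one window.

    Parameters
    ----------
    values : ndarray of shape (n, p)
        Expression values on the working grid.
    window : FeatureWindow
        Time-point indices selecting the feature columns.

    Returns
    -------
    ndarray of shape (n, n)
        Symmetric, diagonal exactly 1, entries in [-1, 1]. Pairs involving
        a zero-variance (flat) profile get correlation 0 off-diagonal.
    """
    values = np.asarray(values, dtype=float)
    idx = np.asarray(window.indices)
    if idx[-1] >= values.shape[1]:
        raise ValueError(
            f"window index {idx[-1]} out of range for {values.shape[1]} points"
        )
    sub = values[:, idx]
    centered = sub - sub.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    flat = norms == 0
    if flat.any():
        corr[flat, :] = 0.0
        corr[:, flat] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    return corr
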