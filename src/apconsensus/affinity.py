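"""Affinity propagation clustering by responsibility/availability message passing.

The clusterer exchanges two kinds of real-valued messages between data
points until a stable set of exemplars emerges: responsibilities r(i, k),
the accumulated evidence that point k should serve as the exemplar for
point i, and availabilities a(i, k), the accumulated evidence that point i
should choose k as its exemplar. Both updates are damped to avoid
oscillation. The number of clusters is not an input; it is controlled
indirectly by the self-similarity ("preference") placed on the diagonal,
here the median of the pairwise similarities, which yields a moderate
number of clusters.

Ties in the similarities are broken by a tiny seeded jitter, following the
original reference implementation's convention, so runs are reproducible
for a fixed seed. Non-convergence within the iteration cap is tolerated:
the current exemplar estimate is returned with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["APConfig", "median_preference", "run_ap"]


@dataclass(frozen=True)
class APConfig:
    """Controls for the message-passing loop.

    damping : fraction of the previous message kept at each update, in [0.5, 1)
    max_iterations : hard cap on message-passing iterations
    convergence_window : iterations the exemplar set must stay unchanged to stop
    preference : explicit diagonal self-similarity; None = median of similarities
    """

    damping: float = 0.9
    max_iterations: int = 1000
    convergence_window: int = 100
    preference: float | None = None

    def __post_init__(self) -> None:
        if not 0.5 <= self.damping < 1:
            raise ValueError(f"damping must be in [0.5, 1), got {self.damping}")
        if self.convergence_window > self.max_iterations:
            raise ValueError("convergence_window cannot exceed max_iterations")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


def median_preference(S: np.ndarray) -> float:
    """Median of the off-diagonal similarities, each unordered pair once."""
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points for a pairwise median")
    iu = np.triu_indices(n, k=1)
    return float(np.median(S[iu]))


def run_ap(
    S: np.ndarray, config: APConfig = APConfig(), seed: int | None = None
) -> np.ndarray:
    """Cluster by affinity propagation on a symmetric similarity matrix.

    Parameters
    ----------
    S : ndarray of shape (n, n)
        Symmetric pairwise similarities. The diagonal is overwritten with
        the preference (explicit, or the median of the off-diagonal
        similarities).
    config : APConfig
        Damping, iteration cap, convergence window, preference.
    seed : int, optional
        Seeds the tie-breaking jitter; fixed seed => identical labels.

    Returns
    -------
    ndarray of shape (n,)
        ``y[i]`` is the index of the exemplar assigned to point i, with
        ``y[y[i]] == y[i]`` (exemplars are their own exemplars).
    """
    S = np.array(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"similarity matrix must be square, got {S.shape}")
    if np.isnan(S).any():
        raise ValueError("similarity matrix contains NaN")
    if not np.allclose(S, S.T, atol=1e-12, rtol=0):
        raise ValueError("similarity matrix must be symmetric")
    n = S.shape[0]
    if n == 1:
        return np.zeros(1, dtype=int)

    pref = config.preference if config.preference is not None else median_preference(S)
    np.fill_diagonal(S, pref)

    # seeded jitter breaks exact ties that would otherwise stall oscillation
    rng = np.random.default_rng(seed)
    scale = np.abs(S).max() or 1.0
    S = S + 1e-12 * scale * rng.standard_normal((n, n))

    damping = config.damping
    A = np.zeros((n, n))
    R = np.zeros((n, n))
    exemplar_flags = np.zeros((config.convergence_window, n), dtype=bool)
    idx = np.arange(n)
    converged = False

    for it in range(config.max_iterations):
        # responsibilities: r(i,k) = s(i,k) - max_{k' != k} [a(i,k') + s(i,k')]
        AS = A + S
        first = np.argmax(AS, axis=1)
        max1 = AS[idx, first]
        AS[idx, first] = -np.inf
        max2 = AS.max(axis=1)
        AS[idx, first] = max1
        Rnew = S - max1[:, None]
        Rnew[idx, first] = S[idx, first] - max2
        R = damping * R + (1 - damping) * Rnew

        # availabilities: a(i,k) = min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)))
        Rp = np.maximum(R, 0)
        np.fill_diagonal(Rp, R.diagonal())
        col = Rp.sum(axis=0)
        Anew = np.minimum(0, col[None, :] - Rp)
        np.fill_diagonal(Anew, col - Rp.diagonal())
        A = damping * A + (1 - damping) * Anew

        exemplars = (A.diagonal() + R.diagonal()) > 0
        exemplar_flags[it % config.convergence_window] = exemplars
        if it >= config.convergence_window - 1 and exemplars.any():
            if (exemplar_flags == exemplars[None, :]).all():
                converged = True
                break

    if not converged:
        logger.warning(
            "affinity propagation did not converge in %d iterations; "
            "returning current exemplar estimate",
            config.max_iterations,
        )

    exemplar_idx = np.flatnonzero((A.diagonal() + R.diagonal()) > 0)
    if exemplar_idx.size == 0:
        # degenerate: fall back to the single best net-evidence point
        exemplar_idx = np.array([int(np.argmax(A.diagonal() + R.diagonal()))])

    # final assignment: nearest exemplar by similarity; exemplars to themselves
    y = exemplar_idx[np.argmax(S[:, exemplar_idx], axis=1)]
    y[exemplar_idx] = exemplar_idx
    return y
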