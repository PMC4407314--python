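"""The end-to-end consensus clusterer as a scikit-learn-style estimator.

Pipeline stages on ``fit``:

1. (optional) cubic-spline resampling of the tau observed points onto the
   doubled 2*tau - 1 grid;
2. for every window size in the chosen range and every feature window of
   that size, a Pearson correlation matrix and one affinity-propagation
   clustering ("vote");
3. two-stage averaging of the votes into the gene-relativity matrix R;
4. threshold sweep over sigma = 0.50 ... 0.80, connected components per
   threshold, Silhouette-based selection of sigma* among the initial
   partitions;
5. refinement of the sigma* partition by the sub-cluster merge rules.

The number of clusters is never supplied: affinity propagation is
self-organizing and the consensus/threshold machinery discovers K.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from . import graph, refine as refine_mod, validity
from .affinity import APConfig, run_ap
from .consensus import VoteAccumulator
from .interpolation import resample_double
from .io import ExpressionMatrix
from .similarity import (
    recommended_window_range,
    sliding_windows,
    subset_windows,
    window_correlation,
)

logger = logging.getLogger(__name__)

__all__ = ["TimeCourseConsensusClustering", "run_pipeline"]


class TimeCourseConsensusClustering(BaseEstimator, ClusterMixin):
    """Interpolation-based affinity-propagation consensus clustering.

    Parameters
    ----------
    interpolate : bool, default=True
        Resample each gene's time course with an interpolating cubic
        spline onto the doubled 2p-1 grid before windowing. Disable for
        simple/short series.
    window_range : tuple (low, high), optional
        Inclusive range of window sizes w. Default: (floor(p/2),
        floor(3p/4)) on the working grid of p points.
    extended : bool, default=False
        Use random time-point subsets instead of contiguous sliding
        windows (recommended only for short series, tau < 10, to raise
        the vote count).
    max_subsets : int, default=200
        Cap on random subsets per window size in extended mode.
    damping, max_iterations, convergence_window : affinity-propagation
        message-passing controls; the preference is always the median
        pairwise similarity.
    sigma_grid : array-like, optional
        Relativity thresholds to sweep; default 0.50, 0.51, ..., 0.80.
    phi : int, optional
        Minor-cluster size threshold for refinement;
        default max(2, ceil(0.01 n)).
    refine : bool, default=True
        Apply the sub-cluster merge rules to the selected partition.
    refine_max_iterations : int, default=500
        Iteration cap for refinement.
    dissimilarity : {"euclidean", "correlation"}, default="euclidean"
        Distance used by the Silhouette selection and validity indices.
    time_stamps : array-like, optional
        Time stamps for the columns of X; default 0, 1, ..., p-1.
    random_state : int, optional
        Single seed fanned out deterministically to every per-window
        affinity-propagation run and to subset sampling.

    Attributes
    ----------
    labels_ : ndarray of shape (n,)
        Final cluster labels, contiguous 1..K in first-appearance order.
    n_clusters_ : int
    relativity_ : RelativityMatrix
        The gene-relativity (aggregated consensus) matrix R.
    sigma_ : float
        Selected relativity threshold sigma*.
    initial_labels_ : ndarray
        The sigma* partition before refinement.
    sweep_ : ThresholdSweep
        Per-threshold partitions and Silhouette values.
    vote_count_ : int
        Total number of affinity-propagation votes aggregated.
    working_time_, working_values_ : the (possibly interpolated) grid the
        pipeline actually clustered on.

    Examples
    --------
    >>> from apconsensus.synthetic import SyntheticSpec, generate
    >>> X, labels = generate(SyntheticSpec(noise_sd=0.0, seed=0))
    >>> model = TimeCourseConsensusClustering(random_state=0).fit(X.values)
    >>> model.n_clusters_
    5
    """

    def __init__(
        self,
        interpolate: bool = True,
        window_range: tuple[int, int] | None = None,
        extended: bool = False,
        max_subsets: int = 200,
        damping: float = 0.9,
        max_iterations: int = 1000,
        convergence_window: int = 100,
        sigma_grid=None,
        phi: int | None = None,
        refine: bool = True,
        refine_max_iterations: int = 500,
        dissimilarity: str = "euclidean",
        time_stamps=None,
        random_state: int | None = None,
    ) -> None:
        self.interpolate = interpolate
        self.window_range = window_range
        self.extended = extended
        self.max_subsets = max_subsets
        self.damping = damping
        self.max_iterations = max_iterations
        self.convergence_window = convergence_window
        self.sigma_grid = sigma_grid
        self.phi = phi
        self.refine = refine
        self.refine_max_iterations = refine_max_iterations
        self.dissimilarity = dissimilarity
        self.time_stamps = time_stamps
        self.random_state = random_state

    # -- helpers ---------------------------------------------------------

    def _as_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D gene x time-point matrix")
        stamps = (
            np.arange(X.shape[1], dtype=float)
            if self.time_stamps is None
            else np.asarray(self.time_stamps, dtype=float)
        )
        ids = [f"g{i}" for i in range(X.shape[0])]
        return ExpressionMatrix(ids, stamps, X)

    def _windows(self, p: int, seed_seq: np.random.SeedSequence):
        low, high = (
            recommended_window_range(p)
            if self.window_range is None
            else self.window_range
        )
        if not 2 <= low <= high <= p:
            raise ValueError(f"invalid window range ({low}, {high}) for p={p}")
        per_size = {}
        if self.extended:
            child_seeds = seed_seq.spawn(high - low + 1)
            for w, child in zip(range(low, high + 1), child_seeds):
                seed = int(child.generate_state(1)[0] % (2**31))
                per_size[w] = subset_windows(p, w, self.max_subsets, seed)
        else:
            for w in range(low, high + 1):
                per_size[w] = sliding_windows(p, w)
        return (low, high), per_size

    # -- estimator API ---------------------------------------------------

    def fit(self, X, y=None):
        """Cluster the genes of ``X`` (rows = genes, columns = time points)."""
        mat = self._as_matrix(X)
        if self.interpolate:
            working = resample_double(mat)
        else:
            working = mat
        n, p = working.values.shape
        self.working_time_ = working.time_stamps
        self.working_values_ = working.values
        self.gene_ids_ = list(working.gene_ids)

        root = np.random.SeedSequence(
            self.random_state if self.random_state is not None else 0
        )
        window_seq, ap_seq = root.spawn(2)
        (low, high), per_size = self._windows(p, window_seq)
        self.window_range_ = (low, high)
        logger.info(
            "clustering %d genes on %d points, windows %d..%d (%s mode)",
            n, p, low, high, "subset" if self.extended else "sliding",
        )

        ap_config = APConfig(
            damping=self.damping,
            max_iterations=self.max_iterations,
            convergence_window=self.convergence_window,
        )
        acc = VoteAccumulator(n)
        total = sum(len(v) for v in per_size.values())
        ap_seeds = iter(ap_seq.spawn(total))
        for w in sorted(per_size):
            for window in per_size[w]:
                S = window_correlation(working.values, window)
                seed = int(next(ap_seeds).generate_state(1)[0] % (2**31))
                labels = run_ap(S, ap_config, seed=seed)
                acc.add(w, labels)
        self.relativity_ = acc.relativity()
        self.vote_count_ = acc.vote_count

        sw = graph.sweep(self.relativity_, self.sigma_grid)
        self.sigma_, initial = graph.select_threshold(
            sw, working.values, self.dissimilarity
        )
        self.sweep_ = sw
        self.initial_labels_ = initial.labels.copy()

        if self.refine:
            final = refine_mod.refine(
                initial,
                self.relativity_,
                working.values,
                phi=self.phi,
                max_iterations=self.refine_max_iterations,
            )
        else:
            final = initial
        self.labels_ = final.labels
        self.n_clusters_ = final.n_clusters
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def score(self, X=None, y=None) -> float:
        """Silhouette index of the fitted partition on the working grid."""
        check_is_fitted(self, "labels_")
        return validity.silhouette(
            self.working_values_, self.labels_, self.dissimilarity
        )

    def validity_report(self, reference: dict[str, str] | None = None):
        """Internal indices of the fitted partition; external too if a
        gene -> class mapping is supplied."""
        check_is_fitted(self, "labels_")
        rep = validity.internal_report(
            self.working_values_, self.labels_, self.dissimilarity
        )
        if reference is not None:
            missing = [g for g in self.gene_ids_ if g not in reference]
            if missing:
                raise ValueError(f"genes missing from reference labels: {missing[:5]}")
            v = [reference[g] for g in self.gene_ids_]
            ext = validity.external_report(self.labels_, v)
            for key, val in ext.as_dict().items():
                setattr(rep, key, val)
        return rep

    def metrics_table(self):
        """Per-threshold table (sigma, K, SI) from the sweep, as a DataFrame."""
        check_is_fitted(self, "sweep_")
        import pandas as pd

        sw = self.sweep_
        return pd.DataFrame(
            {
                "sigma": sw.grid,
                "K": [p.n_clusters for p in sw.partitions],
                "SI": sw.silhouettes,
            }
        )


def run_pipeline(
    matrix: ExpressionMatrix,
    labels: dict[str, str] | None = None,
    **params,
) -> TimeCourseConsensusClustering:
    """Fit the full pipeline on an ExpressionMatrix; thin functional wrapper."""
    model = TimeCourseConsensusClustering(**params)
    model.fit(matrix)
    if labels is not None:
        model.report_ = model.validity_report(labels)
    else:
        model.report_ = model.validity_report()
    return model
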