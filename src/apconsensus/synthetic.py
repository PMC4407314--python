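"""Synthetic time-course expression data with planted cluster structure.

The default generator emulates a cell-cycle-like experiment: K groups of
genes follow phase-shifted sinusoidal prototypes spanning two full cycles
over the sampled window (as in the classic 17-time-point yeast cell-cycle
subset whose five annotated phases peak at different times), plus i.i.d.
Gaussian measurement noise, with per-gene standardization. A
piecewise-switch prototype family (step-like up/down responses at
staggered switch times) mimics developmental time courses such as
sporulation. All outputs are reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .consensus import RelativityMatrix
from .io import ExpressionMatrix

__all__ = ["SyntheticSpec", "generate", "toy_fixture", "FIXTURES"]


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset.

    n_clusters : planted number of groups K
    sizes : genes per group (length K)
    tau : number of observed time points
    time_stamps : optional explicit stamps (default uniform 0..tau-1)
    prototype_family : "sinusoid-phase" or "piecewise-switch"
    noise_sd : SD of additive Gaussian noise (expression is standardized
        per gene afterwards, so this is relative to unit prototype amplitude)
    seed : RNG seed
    """

    n_clusters: int = 5
    sizes: tuple[int, ...] = (20, 20, 20, 20, 20)
    tau: int = 17
    time_stamps: np.ndarray | None = None
    prototype_family: str = "sinusoid-phase"
    noise_sd: float = 0.3
    seed: int = 0
    outlier_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("need at least one cluster")
        if len(self.sizes) != self.n_clusters:
            raise ValueError(
                f"{len(self.sizes)} sizes for {self.n_clusters} clusters"
            )
        if any(s <= 0 for s in self.sizes):
            raise ValueError("cluster sizes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.outlier_fraction <= 1:
            raise ValueError("outlier_fraction must be in [0, 1]")
        if self.time_stamps is None:
            self.time_stamps = np.arange(self.tau, dtype=float)
        else:
            self.time_stamps = np.asarray(self.time_stamps, dtype=float)
            if self.time_stamps.size != self.tau:
                raise ValueError("time_stamps length must equal tau")


def _prototypes(spec: SyntheticSpec) -> np.ndarray:
    t = spec.time_stamps
    span = t[-1] - t[0]
    k = spec.n_clusters
    if spec.prototype_family == "sinusoid-phase":
        # two full cycles across the window, K evenly spaced phases
        phase = 2 * np.pi * np.arange(k) / k
        return np.sin(4 * np.pi * (t - t[0]) / span + phase[:, None])
    if spec.prototype_family == "piecewise-switch":
        # step-like switches at staggered times, alternating up/down
        switch = t[0] + span * (np.arange(k) + 1) / (k + 1)
        sign = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
        return sign[:, None] * np.tanh(2.0 * (t[None, :] - switch[:, None]))
    raise ValueError(f"unknown prototype family {spec.prototype_family!r}")


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Draw one dataset; returns (expression matrix, gene -> class labels)."""
    rng = np.random.default_rng(spec.seed)
    protos = _prototypes(spec)
    rows, gene_ids, labels = [], [], {}
    for k, size in enumerate(spec.sizes):
        cls = f"class{k + 1}"
        for j in range(size):
            gid = f"g{len(gene_ids) + 1:04d}"
            gene_ids.append(gid)
            labels[gid] = cls
            rows.append(protos[k] + rng.normal(0.0, spec.noise_sd, spec.tau))
    values = np.asarray(rows)
    if spec.outlier_fraction > 0:
        n_out = int(round(spec.outlier_fraction * len(gene_ids)))
        out_idx = rng.choice(len(gene_ids), size=n_out, replace=False)
        values[out_idx] = rng.uniform(-2, 2, size=(n_out, spec.tau))
        for i in out_idx:
            labels[gene_ids[i]] = "outlier"
    # per-gene standardization (zero mean, unit SD across time)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    values = (values - mu) / sd
    return ExpressionMatrix(gene_ids, spec.time_stamps.copy(), values), labels


# ---------------------------------------------------------------------------
# hand-constructed fixtures shared across module tests


def _two_block():
    t = np.arange(8, dtype=float)
    up = np.sin(2 * np.pi * t / 7)
    down = -up
    values = np.vstack([up, up, up, down, down, down])
    ids = [f"g{i}" for i in range(1, 7)]
    labels = {g: ("A" if i < 3 else "B") for i, g in enumerate(ids)}
    return ExpressionMatrix(ids, t, values), labels


def _bridge_06():
    # two tight 0.9-relativity blocks joined by a single 0.6 bridge edge:
    # one component at sigma <= 0.6, two components at sigma > 0.6
    n = 6
    R = np.full((n, n), 0.1)
    for block in (range(3), range(3, 6)):
        for i in block:
            for j in block:
                R[i, j] = 0.9
    R[2, 3] = R[3, 2] = 0.6
    np.fill_diagonal(R, 1.0)
    return RelativityMatrix(R, vote_count=10)


def _rule2_anticorrelated():
    # 2 major clusters + one 2-gene sub-cluster anticorrelated with both:
    # the sub-cluster must survive Rule 2.1
    t = np.arange(10, dtype=float)
    a = np.sin(2 * np.pi * t / 9)
    b = np.cos(2 * np.pi * t / 9)
    sub = -(a + b) / np.linalg.norm(a + b)  # anticorrelated with both means
    values = np.vstack([a] * 4 + [b] * 4 + [sub, sub])
    ids = [f"g{i}" for i in range(1, 11)]
    labels = np.array([1] * 4 + [2] * 4 + [3] * 2)
    return ExpressionMatrix(ids, t, values), labels


FIXTURES = {
    "two-block": _two_block,
    "bridge-0.6": _bridge_06,
    "rule2-anticorrelated": _rule2_anticorrelated,
}


def toy_fixture(name: str):
    """Fetch a registered hand-built fixture by name."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
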