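import numpy as np
import pytest

from apconsensus.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """4 genes x 6 points, smooth distinct profiles on an irregular grid."""
    t = np.array([0.0, 0.5, 2.0, 5.0, 7.0, 9.0])
    values = np.vstack(
        [
            np.sin(t),
            np.cos(t),
            0.3 * t - 1.0,
            np.exp(-0.3 * t),
        ]
    )
    return ExpressionMatrix(["a", "b", "c", "d"], t, values)


def exhaustive_ap_oracle(S, preference):
    """Best partition over every exemplar subset, by net similarity.

    Scores each non-empty exemplar subset E by
    sum_i max_{e in E} S(i, e) for i outside E plus the preference for
    each exemplar, keeps the best score per induced co-cluster partition,
    and returns (co-cluster matrix of the optimum, margin to the best
    scoring distinct partition).
    """
    import itertools

    n = S.shape[0]
    Sd = S.copy()
    np.fill_diagonal(Sd, preference)
    per_partition = {}
    for r in range(1, n + 1):
        for subset in itertools.combinations(range(n), r):
            E = np.array(subset)
            assign = E[np.argmax(Sd[:, E], axis=1)]
            assign[E] = E
            score = Sd[np.arange(n), assign].sum()
            key = tuple((assign[:, None] == assign[None, :]).ravel())
            per_partition[key] = max(per_partition.get(key, -np.inf), score)
    ranked = sorted(per_partition.items(), key=lambda kv: -kv[1])
    margin = ranked[0][1] - (ranked[1][1] if len(ranked) > 1 else -np.inf)
    co = np.array(ranked[0][0]).reshape(n, n)
    return co, margin
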