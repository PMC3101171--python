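import numpy as np
import pytest

from tfcluster import (
    ConnectivityStats,
    ExpressionMatrix,
    Neighborhood,
    SCCM,
    build_sccm,
)


@pytest.fixture
def toy_expr():
    """5-sample toy: TF t plus four genes with known Spearman rho to t
    (g1: 1.0, g2: -1.0, g3: 0.8, g4: 0.8)."""
    return ExpressionMatrix(
        gene_ids=("t", "g1", "g2", "g3", "g4"),
        sample_ids=("s1", "s2", "s3", "s4", "s5"),
        values=np.array(
            [
                [1, 2, 3, 4, 5],
                [2, 3, 4, 5, 6],
                [5, 4, 3, 2, 1],
                [1, 3, 2, 5, 4],
                [2, 1, 4, 3, 5],
            ],
            dtype=float,
        ),
    )


@pytest.fixture
def six_tf_sccm():
    """Hand-simulatable 6-TF connectivity matrix. With mu=10, delta=2 and
    theta=(2.0, 1.5, 1.0) the taus are (14, 13, 12) and the decomposition
    is [{T1,T2,T3,T4}, {T5,T6}]."""
    ids = ("T1", "T2", "T3", "T4", "T5", "T6")
    pairs = {
        ("T1", "T2"): 20,
        ("T1", "T3"): 16,
        ("T2", "T3"): 14,
        ("T1", "T4"): 15,
        ("T2", "T4"): 14,
        ("T3", "T4"): 13,
        ("T1", "T5"): 15,
        ("T2", "T5"): 13,
        ("T5", "T6"): 18,
    }
    idx = {t: i for i, t in enumerate(ids)}
    entries = {(idx[a], idx[b]): v for (a, b), v in pairs.items()}
    return SCCM(tf_ids=ids, omega=50, entries=entries)


@pytest.fixture
def six_tf_stats():
    return ConnectivityStats(mu=10.0, delta=2.0, n_nonzero=9)


def random_neighborhoods(rng, p=None, omega=None, n_genes=None):
    """Random per-TF neighborhoods over a small gene universe."""
    p = p or int(rng.integers(3, 21))
    n_genes = n_genes or int(rng.integers(20, 61))
    omega = omega or int(rng.integers(2, 11))
    omega = min(omega, n_genes)
    genes = np.array([f"g{k}" for k in range(n_genes)])
    nbs = []
    for i in range(p):
        members = rng.choice(genes, size=omega, replace=False)
        scores = np.sort(rng.uniform(-1, 1, size=omega))[::-1]
        nbs.append(
            Neighborhood(
                tf_id=f"tf{i}",
                members=tuple(members),
                scores=tuple(float(s) for s in scores),
            )
        )
    return nbs


def random_sccm(rng, **kw):
    """Random SCCM built from random neighborhoods (may be empty)."""
    return build_sccm(random_neighborhoods(rng, **kw))
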