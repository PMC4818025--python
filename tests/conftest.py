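import numpy as np
import pandas as pd
import pytest

from wsnf.network import RegulatoryNetwork
from wsnf.preprocess import ExpressionMatrix


@pytest.fixture
def chain_net():
    """Three nodes with edges A->B, A->C, B->C (hand-solved rank fixture)."""
    return RegulatoryNetwork(
        classes={"A": "TF", "B": "TF", "C": "mRNA"},
        edges={("A", "B"), ("A", "C"), ("B", "C")},
    )


def random_network(rng: np.random.Generator, n: int, p: float) -> RegulatoryNetwork:
    """Erdos-Renyi-style directed network with random node classes."""
    names = [f"f{i}" for i in range(n)]
    klasses = rng.choice(["miRNA", "TF", "mRNA"], size=n)
    classes = dict(zip(names, klasses))
    mask = rng.random((n, n)) < p
    np.fill_diagonal(mask, False)
    edges = {(names[i], names[j]) for i, j in zip(*np.nonzero(mask))}
    return RegulatoryNetwork(classes=classes, edges=edges)


def ensure_all_regulated(rng: np.random.Generator, net: RegulatoryNetwork) -> RegulatoryNetwork:
    """Add edges so every node has at least one regulator (no self-loops)."""
    edges = set(net.edges)
    names = net.features
    for f, deg in net.in_degree().items():
        if deg == 0:
            others = [g for g in names if g != f]
            edges.add((others[rng.integers(len(others))], f))
    return RegulatoryNetwork(classes=dict(net.classes), edges=edges)


def make_expr(values: np.ndarray, view: str = "genes", prefix: str = "g") -> ExpressionMatrix:
    p, n = values.shape
    return ExpressionMatrix(
        values=pd.DataFrame(
            values,
            index=[f"{prefix}{i}" for i in range(p)],
            columns=[f"S{j}" for j in range(n)],
        ),
        view=view,
    )
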