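import numpy as np
import pytest

from rwrknn.core_data import (
    AssociationMatrix,
    DiseaseDAG,
    EntityRegistry,
)


@pytest.fixture
def chain_dag() -> DiseaseDAG:
    """d -> t1 -> t2 ancestor chain."""
    return DiseaseDAG(disease="d", edges=frozenset({("d", "t1"), ("t1", "t2")}))


@pytest.fixture
def diamond_dag() -> DiseaseDAG:
    """d -> {t1, t2} -> t3 diamond."""
    return DiseaseDAG(
        disease="d",
        edges=frozenset({("d", "t1"), ("d", "t2"), ("t1", "t3"), ("t2", "t3")}),
    )


@pytest.fixture
def tiny_assoc() -> AssociationMatrix:
    """3 circRNAs x 3 diseases with one zero-degree circRNA."""
    values = np.array([[1, 1, 0], [0, 1, 1], [0, 0, 0]], dtype=np.int8)
    return AssociationMatrix(
        values,
        EntityRegistry(("c1", "c2", "c3")),
        EntityRegistry(("d1", "d2", "d3")),
    )


def random_dag_edges(rng: np.random.Generator, n_terms: int, edge_prob: float):
    """Random acyclic child->parent edge set over terms n0..n{k-1}; edges only
    go from lower to higher index, so acyclicity holds by construction."""
    edges = set()
    for child in range(n_terms):
        for parent in range(child + 1, n_terms):
            if rng.random() < edge_prob:
                edges.add((f"n{child}", f"n{parent}"))
    return frozenset(edges)
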