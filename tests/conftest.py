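"""Shared fixtures: toy ontologies and random-DAG generators."""
from __future__ import annotations

import numpy as np
import pytest

from hecasd.ontology import Namespace, OntologyGraph, RelationType
from hecasd.term_similarity import build_ic_table

#: Five-term DAG: root R; A is_a R; B is_a R; C is_a A, C part_of B; D is_a C.
TOY_EDGES = [
    ("A", "R", RelationType.IS_A),
    ("B", "R", RelationType.IS_A),
    ("C", "A", RelationType.IS_A),
    ("C", "B", RelationType.PART_OF),
    ("D", "C", RelationType.IS_A),
]

#: Three-term chain: R; A is_a R; B is_a A.
CHAIN_EDGES = [
    ("A", "R", RelationType.IS_A),
    ("B", "A", RelationType.IS_A),
]


@pytest.fixture(scope="session")
def toy_graph() -> OntologyGraph:
    return OntologyGraph(["R", "A", "B", "C", "D"], TOY_EDGES)


@pytest.fixture(scope="session")
def chain_graph() -> OntologyGraph:
    return OntologyGraph(["R", "A", "B"], CHAIN_EDGES)


@pytest.fixture(scope="session")
def toy_ic(toy_graph):
    return build_ic_table(toy_graph)


def random_dag(
    rng: np.random.Generator,
    n_terms: int,
    second_parent_prob: float = 0.3,
    part_of_prob: float = 0.3,
) -> OntologyGraph:
    """Random single-rooted DAG where term i attaches to earlier terms."""
    names = [f"N{i:03d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        parent = names[int(rng.integers(i))]
        rel = RelationType.PART_OF if rng.random() < part_of_prob else RelationType.IS_A
        edges.append((names[i], parent, rel))
        if i > 1 and rng.random() < second_parent_prob:
            second = names[int(rng.integers(i))]
            if second != parent:
                rel2 = (
                    RelationType.PART_OF
                    if rng.random() < part_of_prob
                    else RelationType.IS_A
                )
                edges.append((names[i], second, rel2))
    return OntologyGraph({n: Namespace.BP for n in names}, edges)
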