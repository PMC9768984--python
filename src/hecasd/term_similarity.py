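"""Term-level semantic similarity on the ontology DAG.

Four measures are provided:

* **Resnik** — the information content (IC) of the most informative
  common ancestor (MICA), where ``IC(t) = -ln Pro(t)`` and ``Pro(t)`` is
  the fraction of namespace terms that lie at or below ``t``.
* **Relevance** — Resnik rescaled by the MICA's rarity and the two
  terms' own IC: ``2 IC(MICA) (1 - Pro(MICA)) / (IC(t1) + IC(t2))``.
* **Wang** — the graph-based measure: each term in the focus term's
  ancestor sub-DAG receives an S-value, the maximal product of edge
  weights along a rootward path from the focus (weights 0.8 for is-a,
  0.6 for part-of), and two terms are compared by how much S-value mass
  their sub-DAGs share.
* **HGS** — the hybrid variant: identical aggregation to Wang, but the
  weight of an edge into parent ``a`` is driven by ``a``'s child count
  instead of a fixed constant, ``w = 1/(c + n_children(a)) + d_rel``
  with ``d_rel = 0.4`` (is-a), ``0.3`` (part-of) and ``c = 0.67``.
  Busy parents therefore pass less semantic value to each child.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import networkx as nx

from .ontology import OntologyGraph, OntologyError, RelationType

logger = logging.getLogger(__name__)

__all__ = [
    "WeightMode",
    "WeightScheme",
    "ICTable",
    "SValueMap",
    "build_ic_table",
    "mica",
    "resnik_sim",
    "relevance_sim",
    "edge_weight",
    "svalues",
    "graph_term_sim",
]


class WeightMode(str, Enum):
    WANG_FIXED = "wang_fixed"
    HGS = "hgs"


@dataclass(frozen=True)
class WeightScheme:
    """Edge-weight parameters for the Wang-family S-value recursion.

    ``WANG_FIXED`` uses the canonical per-relation constants; ``HGS``
    replaces them with a child-count-penalized weight per parent term.
    """

    mode: WeightMode = WeightMode.WANG_FIXED
    w_isa: float = 0.8
    w_partof: float = 0.6
    d_isa: float = 0.4
    d_partof: float = 0.3
    c: float = 0.67

    def __post_init__(self) -> None:
        for label, value in (
            ("w_isa", self.w_isa),
            ("w_partof", self.w_partof),
            ("d_isa", self.d_isa),
            ("d_partof", self.d_partof),
            ("c", self.c),
        ):
            if not 0.0 < value < 1.0:
                raise OntologyError(f"weight parameter {label}={value} outside (0,1)")

    @classmethod
    def wang(cls, w_isa: float = 0.8, w_partof: float = 0.6) -> "WeightScheme":
        return cls(mode=WeightMode.WANG_FIXED, w_isa=w_isa, w_partof=w_partof)

    @classmethod
    def hgs(
        cls, d_isa: float = 0.4, d_partof: float = 0.3, c: float = 0.67
    ) -> "WeightScheme":
        return cls(mode=WeightMode.HGS, d_isa=d_isa, d_partof=d_partof, c=c)


@dataclass(frozen=True)
class ICTable:
    """Per-term annotation probability and information content (nats)."""

    pro: dict[str, float]
    ic: dict[str, float]

    @property
    def max_ic(self) -> float:
        return max(self.ic.values())


@dataclass(frozen=True)
class SValueMap:
    """S-values of every term in the focus term's ancestor sub-DAG."""

    focus: str
    svalue: dict[str, float]

    @property
    def sv(self) -> float:
        """Total semantic value SV: the sum of all S-values."""
        return sum(self.svalue.values())


def build_ic_table(graph: OntologyGraph) -> ICTable:
    """Pro(t) = descendant_count(t) / |terms|; IC(t) = -ln Pro(t).

    The descendant count includes the term itself, so every Pro is in
    (0, 1], the root has Pro 1 and IC 0, and IC is finite at leaves.
    """
    n = len(graph)
    if n == 0:
        raise OntologyError("cannot build an IC table for an empty graph")
    pro = {t: graph.descendant_count(t) / n for t in graph}
    ic = {t: -math.log(p) for t, p in pro.items()}
    return ICTable(pro=pro, ic=ic)


def mica(graph: OntologyGraph, ic: ICTable, t1: str, t2: str) -> str:
    """Most informative common ancestor; IC ties go to the smallest id."""
    common = graph.ancestors(t1, include_self=True) & graph.ancestors(
        t2, include_self=True
    )
    if not common:
        raise OntologyError(
            f"terms {t1!r} and {t2!r} share no ancestor; graph is not single-rooted"
        )
    return min(common, key=lambda t: (-ic.ic[t], t))


def resnik_sim(
    graph: OntologyGraph,
    ic: ICTable,
    t1: str,
    t2: str,
    *,
    normalize: bool = False,
) -> float:
    """IC of the MICA; optionally divided by the namespace's maximum IC."""
    value = ic.ic[mica(graph, ic, t1, t2)]
    if normalize:
        top = ic.max_ic
        value = value / top if top > 0 else 0.0
    return value


def relevance_sim(graph: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    """2 IC(MICA) (1 - Pro(MICA)) / (IC(t1) + IC(t2)); 0 for the root pair."""
    anc = mica(graph, ic, t1, t2)
    denom = ic.ic[t1] + ic.ic[t2]
    if denom == 0.0:
        logger.info("relevance_sim(%s, %s): both terms are the root; returning 0", t1, t2)
        return 0.0
    return 2.0 * ic.ic[anc] * (1.0 - ic.pro[anc]) / denom


def edge_weight(
    graph: OntologyGraph,
    parent: str,
    relation: RelationType,
    scheme: WeightScheme,
) -> float:
    """Semantic weight of an edge into ``parent`` with the given relation."""
    if scheme.mode is WeightMode.WANG_FIXED:
        return scheme.w_isa if relation is RelationType.IS_A else scheme.w_partof
    nc = len(graph.children(parent))
    if nc == 0:
        raise OntologyError(
            f"term {parent!r} appears as an edge parent but has no children"
        )
    d_rel = scheme.d_isa if relation is RelationType.IS_A else scheme.d_partof
    w = 1.0 / (scheme.c + nc) + d_rel
    if not w < 1.0:
        raise OntologyError(
            f"HGS weight {w} for parent {parent!r} (children={nc}) is not < 1"
        )
    return w


def svalues(graph: OntologyGraph, t: str, scheme: WeightScheme) -> SValueMap:
    """Contributed semantic value of every term in ``t``'s ancestor sub-DAG.

    S(t) = 1; for each ancestor ``a``, S(a) is the maximum over the
    sub-DAG edges ``u -> a`` of ``edge_weight(a, rel) * S(u)``; computed
    by dynamic programming in topological order (children first).
    """
    sub = graph.induced_subdag(t)
    into: dict[str, list[tuple[str, RelationType]]] = {}
    dag = nx.MultiDiGraph()
    dag.add_nodes_from(sub.terms)
    for child, parent, rel in sub.edges:
        into.setdefault(parent, []).append((child, rel))
        dag.add_edge(child, parent)
    s: dict[str, float] = {}
    for node in nx.topological_sort(dag):
        if node == sub.focus:
            s[node] = 1.0
            continue
        s[node] = max(
            edge_weight(graph, node, rel, scheme) * s[child]
            for child, rel in into[node]
        )
    return SValueMap(focus=sub.focus, svalue=s)


def graph_term_sim(
    graph: OntologyGraph, t1: str, t2: str, scheme: WeightScheme
) -> float:
    """Wang-family similarity: shared S-value mass over total S-value mass."""
    s1 = svalues(graph, t1, scheme)
    s2 = svalues(graph, t2, scheme)
    common = s1.svalue.keys() & s2.svalue.keys()
    numerator = sum(s1.svalue[t] + s2.svalue[t] for t in common)
    return numerator / (s1.sv + s2.sv)
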