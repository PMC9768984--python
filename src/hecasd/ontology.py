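"""Typed-edge ontology graphs: loading, validation, and DAG queries.

The similarity machinery works on a directed acyclic graph of ontology
terms with edges pointing child -> parent.  Only the two relation types
that carry semantics in the Wang family of measures (``is_a`` and
``part_of``) are kept; every other OBO relation is dropped on load, as
are obsolete terms.  Each namespace must have exactly one root after
filtering, so that the root's annotation probability is well defined.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "Namespace",
    "RelationType",
    "OntologyGraph",
    "TermSubDAG",
    "OntologyError",
    "OboParseError",
    "CycleError",
    "UnknownTermError",
    "load_obo",
    "load_edge_tsv",
]


class OntologyError(ValueError):
    """Base class for ontology validation failures."""


class OboParseError(OntologyError):
    """Raised when an OBO file cannot be parsed."""


class CycleError(OntologyError):
    """Raised when the child->parent edge set contains a directed cycle."""


class UnknownTermError(KeyError):
    """Raised when a term id is not present in the graph."""


class Namespace(str, Enum):
    BP = "biological_process"
    MF = "molecular_function"
    CC = "cellular_component"

    @classmethod
    def coerce(cls, value: "Namespace | str") -> "Namespace":
        if isinstance(value, Namespace):
            return value
        key = str(value).strip()
        if key.upper() in cls.__members__:
            return cls[key.upper()]
        for member in cls:
            if member.value == key.lower():
                return member
        raise OntologyError(f"unknown namespace {value!r}; expected BP, MF or CC")


class RelationType(str, Enum):
    IS_A = "is_a"
    PART_OF = "part_of"

    @classmethod
    def coerce(cls, value: "RelationType | str") -> "RelationType":
        if isinstance(value, RelationType):
            return value
        key = str(value).strip().lower().replace("-", "_")
        for member in cls:
            if member.value == key:
                return member
        raise OntologyError(f"unknown relation {value!r}; expected is_a or part_of")


Edge = tuple[str, str, RelationType]


@dataclass(frozen=True)
class TermSubDAG:
    """A focus term with its ancestor closure and the induced typed edges."""

    focus: str
    terms: frozenset[str]
    edges: frozenset[Edge]


class OntologyGraph:
    """Validated acyclic term graph with typed child->parent edges.

    Parameters
    ----------
    terms
        Mapping from term id to :class:`Namespace` (or an iterable of
        term ids, in which case every term is taken to be BP).
    edges
        Iterable of ``(child_id, parent_id, relation)`` triples.
    names
        Optional mapping term id -> human-readable name.
    alt_ids
        Optional mapping of alternative (merged) ids to canonical ids;
        queries resolve through it transparently.
    """

    def __init__(
        self,
        terms: Mapping[str, Namespace] | Iterable[str],
        edges: Iterable[tuple[str, str, RelationType | str]],
        *,
        names: Mapping[str, str] | None = None,
        alt_ids: Mapping[str, str] | None = None,
    ) -> None:
        if isinstance(terms, Mapping):
            self._namespace = {t: Namespace.coerce(ns) for t, ns in terms.items()}
        else:
            self._namespace = {t: Namespace.BP for t in terms}
        if not self._namespace:
            raise OntologyError("ontology graph has no terms")
        self._names = dict(names or {})
        self._alt = dict(alt_ids or {})
        self._g = nx.MultiDiGraph()
        self._g.add_nodes_from(self._namespace)
        for child, parent, rel in edges:
            rel = RelationType.coerce(rel)
            for endpoint in (child, parent):
                if endpoint not in self._namespace:
                    raise OntologyError(
                        f"edge ({child} -> {parent}) references unknown term {endpoint!r}"
                    )
            if self._namespace[child] is not self._namespace[parent]:
                raise OntologyError(
                    f"edge ({child} -> {parent}) crosses namespaces "
                    f"{self._namespace[child].name} -> {self._namespace[parent].name}"
                )
            self._g.add_edge(child, parent, key=rel.value, relation=rel)
        self._validate()
        self._desc_count: dict[str, int] = {}

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self._g):
            cycle = nx.find_cycle(self._g)
            path = " -> ".join(str(u) for u, _, _ in cycle) + f" -> {cycle[0][0]}"
            raise CycleError(f"ontology contains a cycle: {path}")
        self._roots: dict[Namespace, str] = {}
        by_ns: dict[Namespace, list[str]] = {}
        for t, ns in self._namespace.items():
            if self._g.out_degree(t) == 0:
                by_ns.setdefault(ns, []).append(t)
        for ns in set(self._namespace.values()):
            roots = sorted(by_ns.get(ns, []))
            if len(roots) != 1:
                raise OntologyError(
                    f"namespace {ns.name} must have exactly one root, found "
                    f"{len(roots)}: {roots}"
                )
            self._roots[ns] = roots[0]

    # -- basic queries ------------------------------------------------

    def __contains__(self, term: str) -> bool:
        return self.resolve(term, strict=False) is not None

    def __len__(self) -> int:
        return len(self._namespace)

    def __iter__(self) -> Iterator[str]:
        return iter(self._namespace)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._namespace)

    @property
    def edges(self) -> frozenset[Edge]:
        return frozenset(
            (u, v, data["relation"]) for u, v, data in self._g.edges(data=True)
        )

    def namespace_of(self, term: str) -> Namespace:
        return self._namespace[self.resolve(term)]

    def name_of(self, term: str) -> str:
        term = self.resolve(term)
        return self._names.get(term, term)

    def root(self, namespace: Namespace | str | None = None) -> str:
        if namespace is None:
            if len(self._roots) != 1:
                raise OntologyError("graph spans several namespaces; pass one")
            return next(iter(self._roots.values()))
        return self._roots[Namespace.coerce(namespace)]

    def resolve(self, term: str, *, strict: bool = True) -> str | None:
        """Map an id (possibly an alt_id) to its canonical term id."""
        if term in self._namespace:
            return term
        if term in self._alt and self._alt[term] in self._namespace:
            return self._alt[term]
        if strict:
            raise UnknownTermError(f"unknown term id {term!r}")
        return None

    # -- DAG navigation -----------------------------------------------

    def parents(self, term: str) -> frozenset[str]:
        return frozenset(self._g.successors(self.resolve(term)))

    def children(self, term: str) -> frozenset[str]:
        """Direct children of ``term`` (terms with an edge into it)."""
        return frozenset(self._g.predecessors(self.resolve(term)))

    def parent_edges(self, term: str) -> list[tuple[str, RelationType]]:
        term = self.resolve(term)
        return [
            (v, data["relation"]) for _, v, data in self._g.out_edges(term, data=True)
        ]

    def child_edges(self, term: str) -> list[tuple[str, RelationType]]:
        term = self.resolve(term)
        return [
            (u, data["relation"]) for u, _, data in self._g.in_edges(term, data=True)
        ]

    def ancestors(self, term: str, include_self: bool = False) -> frozenset[str]:
        """Transitive closure over child->parent edges of both relation types."""
        term = self.resolve(term)
        anc = nx.descendants(self._g, term)  # edges point rootward
        if include_self:
            anc = anc | {term}
        return frozenset(anc)

    def descendants(self, term: str, include_self: bool = False) -> frozenset[str]:
        term = self.resolve(term)
        desc = nx.ancestors(self._g, term)
        if include_self:
            desc = desc | {term}
        return frozenset(desc)

    def descendant_count(self, term: str) -> int:
        """Number of terms whose ancestor closure contains ``term``.

        The count includes the term itself, so every leaf scores 1 and
        the namespace root scores the namespace size.
        """
        term = self.resolve(term)
        if term not in self._desc_count:
            self._desc_count[term] = len(self.descendants(term, include_self=True))
        return self._desc_count[term]

    def induced_subdag(self, term: str) -> TermSubDAG:
        """The focus term, its ancestor closure, and all induced edges."""
        term = self.resolve(term)
        closure = self.ancestors(term, include_self=True)
        induced = frozenset(
            (u, v, data["relation"])
            for u, v, data in self._g.edges(data=True)
            if u in closure and v in closure
        )
        return TermSubDAG(focus=term, terms=closure, edges=induced)

    def subgraph_view(self, terms: frozenset[str]) -> nx.MultiDiGraph:
        return self._g.subgraph(terms)

    # -- serialization ------------------------------------------------

    def to_edge_tsv(self) -> str:
        lines = [
            f"{u}\t{v}\t{rel.value}"
            for u, v, rel in sorted(self.edges, key=lambda e: (e[0], e[1], e[2].value))
        ]
        return "\n".join(lines) + "\n"

    def stats(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for ns in sorted({n.name for n in self._namespace.values()}):
            members = {t for t, n in self._namespace.items() if n.name == ns}
            n_edges = sum(1 for u, _v, _r in self.edges if u in members)
            out[ns] = {"terms": len(members), "edges": n_edges}
        return out


def load_obo(path: str, namespace: Namespace | str = Namespace.BP) -> OntologyGraph:
    """Read an OBO 1.2/1.4 file and return one namespace's validated graph.

    Obsolete terms are skipped; edges other than ``is_a``/``part_of``
    are dropped with a log line; ``alt_id`` entries are mapped to their
    canonical id.
    """
    ns = Namespace.coerce(namespace)
    try:
        raw = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # obonet raises assorted parse errors
        raise OboParseError(f"cannot parse OBO file {path!r}: {exc}") from exc
    keep = {
        node
        for node, data in raw.nodes(data=True)
        if data.get("namespace", Namespace.BP.value) == ns.value
    }
    if not keep:
        raise OntologyError(f"no non-obsolete {ns.name} terms found in {path!r}")
    terms = {node: ns for node in keep}
    names = {
        node: raw.nodes[node].get("name", node)
        for node in keep
    }
    edges: list[tuple[str, str, RelationType]] = []
    dropped = 0
    for u, v, key in raw.edges(keys=True):
        if u not in keep or v not in keep:
            continue
        if key in (RelationType.IS_A.value, RelationType.PART_OF.value):
            edges.append((u, v, RelationType(key)))
        else:
            dropped += 1
            logger.info("dropping %s edge %s -> %s (relation not used)", key, u, v)
    if dropped:
        logger.info("dropped %d edges with unused relation types", dropped)
    alt: dict[str, str] = {}
    for node in keep:
        for alt_id in raw.nodes[node].get("alt_id", []):
            alt[alt_id] = node
    return OntologyGraph(terms, edges, names=names, alt_ids=alt)


def load_edge_tsv(
    source: str | Iterable[str], namespace: Namespace | str = Namespace.BP
) -> OntologyGraph:
    """Read a three-column ``child<TAB>parent<TAB>relation`` edge list.

    ``source`` is a path or an iterable of lines.  All terms are placed
    in the given namespace.  Intended for small fixtures and synthetic
    ontologies.
    """
    ns = Namespace.coerce(namespace)
    if isinstance(source, str):
        with open(source, "rt", encoding="utf-8") as handle:
            lines = handle.readlines()
    else:
        lines = list(source)
    edges: list[tuple[str, str, RelationType]] = []
    terms: set[str] = set()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise OboParseError(
                f"line {lineno}: expected 3 tab-separated fields, got {len(parts)}"
            )
        child, parent, rel = parts
        edges.append((child, parent, RelationType.coerce(rel)))
        terms.update((child, parent))
    return OntologyGraph({t: ns for t in sorted(terms)}, edges)
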