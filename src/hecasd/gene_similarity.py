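"""Gene-level functional similarity from term-level semantics.

A gene is represented by its set of annotation terms (one namespace).
For a gene pair, every term of one gene is compared with every term of
the other (the term-pair matrix), and the matrix is collapsed to a
single number by best-match-average (BMA, the default) or by the global
maximum.  Doing this for all unordered pairs yields the symmetric gene
functional similarity matrix, whose row *i* doubles as gene *i*'s
feature vector for the downstream classifiers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import Namespace, OntologyGraph, OntologyError
from .term_similarity import (
    ICTable,
    WeightMode,
    WeightScheme,
    build_ic_table,
    graph_term_sim,
    relevance_sim,
    resnik_sim,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MEASURES",
    "AnnotationSet",
    "TermSimMatrix",
    "GeneSimilarityMatrix",
    "SemanticSimilarity",
    "term_sim_matrix",
    "combine_bma",
    "combine_max",
    "build_gene_matrix",
]

MEASURES = ("resnik", "relevance", "wang", "hgs")

#: GAF 2.x column positions (0-based) used by :meth:`AnnotationSet.from_gaf`.
_GAF_SYMBOL, _GAF_GOID, _GAF_EVIDENCE, _GAF_ASPECT = 2, 4, 6, 8
_ASPECT_CODE = {Namespace.BP: "P", Namespace.MF: "F", Namespace.CC: "C"}


@dataclass
class AnnotationSet:
    """Gene -> non-empty set of ontology term ids (single namespace).

    ``dropped`` records genes whose every term was missing from the
    graph; ``skipped_terms`` counts term references discarded because
    they are unknown to the loaded ontology.
    """

    annotations: dict[str, frozenset[str]]
    evidence: dict[tuple[str, str], str] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)
    skipped_terms: int = 0

    def __post_init__(self) -> None:
        for gene, terms in self.annotations.items():
            if not terms:
                raise OntologyError(f"gene {gene!r} has an empty annotation set")

    def __contains__(self, gene: str) -> bool:
        return gene in self.annotations

    def __len__(self) -> int:
        return len(self.annotations)

    @property
    def genes(self) -> list[str]:
        return sorted(self.annotations)

    def terms_of(self, gene: str) -> frozenset[str]:
        try:
            return self.annotations[gene]
        except KeyError:
            raise OntologyError(f"gene {gene!r} has no annotations") from None

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str]],
        graph: OntologyGraph,
        evidence: Mapping[tuple[str, str], str] | None = None,
    ) -> "AnnotationSet":
        """Build from (gene, term) pairs, resolving terms against ``graph``."""
        raw: dict[str, set[str]] = {}
        seen: set[str] = set()
        skipped = 0
        kept_evidence: dict[tuple[str, str], str] = {}
        evidence = dict(evidence or {})
        for gene, term in records:
            seen.add(gene)
            resolved = graph.resolve(term, strict=False)
            if resolved is None:
                skipped += 1
                continue
            raw.setdefault(gene, set()).add(resolved)
            if (gene, term) in evidence:
                kept_evidence[(gene, resolved)] = evidence[(gene, term)]
        dropped = sorted(seen - raw.keys())
        annotations = {g: frozenset(terms) for g, terms in raw.items()}
        if skipped:
            logger.info("skipped %d annotation terms absent from the ontology", skipped)
        return cls(
            annotations=annotations,
            evidence=kept_evidence,
            dropped=dropped,
            skipped_terms=skipped,
        )

    @classmethod
    def from_gaf(
        cls,
        path: str,
        graph: OntologyGraph,
        namespace: Namespace | str = Namespace.BP,
    ) -> "AnnotationSet":
        """Read a GAF 2.1/2.2 file, keeping one aspect's annotations."""
        aspect = _ASPECT_CODE[Namespace.coerce(namespace)]
        records: list[tuple[str, str]] = []
        evidence: dict[tuple[str, str], str] = {}
        with open(path, "rt", encoding="utf-8") as handle:
            for line in handle:
                if not line.strip() or line.startswith("!"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) <= _GAF_ASPECT:
                    raise OntologyError(
                        f"GAF line has {len(cols)} columns, expected >= {_GAF_ASPECT + 1}"
                    )
                if cols[_GAF_ASPECT] != aspect:
                    continue
                gene, term = cols[_GAF_SYMBOL], cols[_GAF_GOID]
                records.append((gene, term))
                evidence[(gene, term)] = cols[_GAF_EVIDENCE]
        return cls.from_records(records, graph, evidence=evidence)

    @classmethod
    def from_tsv(cls, path: str, graph: OntologyGraph) -> "AnnotationSet":
        """Read a two-column ``gene<TAB>term`` file."""
        records: list[tuple[str, str]] = []
        with open(path, "rt", encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise OntologyError(
                        f"line {lineno}: expected 2 tab-separated fields, got {len(parts)}"
                    )
                records.append((parts[0], parts[1]))
        return cls.from_records(records, graph)

    def to_tsv(self) -> str:
        lines = [
            f"{gene}\t{term}"
            for gene in self.genes
            for term in sorted(self.annotations[gene])
        ]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class TermSimMatrix:
    """Term-pair similarity matrix for one gene pair."""

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise OntologyError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.rows)}, {len(self.cols)}) term labels"
            )


class SemanticSimilarity:
    """Cached term-level similarity engine for one measure.

    Parameters
    ----------
    graph
        The validated single-namespace ontology.
    measure
        One of ``resnik``, ``relevance``, ``wang``, ``hgs``.
    scheme
        Optional override of the edge-weight parameters (graph-based
        measures only).
    normalize_resnik
        Divide Resnik values by the namespace's maximum IC so gene-level
        aggregation stays in [0, 1].  On by default.
    """

    def __init__(
        self,
        graph: OntologyGraph,
        measure: str = "wang",
        scheme: WeightScheme | None = None,
        *,
        normalize_resnik: bool = True,
    ) -> None:
        if measure not in MEASURES:
            raise OntologyError(f"unknown measure {measure!r}; expected one of {MEASURES}")
        self.graph = graph
        self.measure = measure
        self.normalize_resnik = normalize_resnik
        if scheme is None:
            scheme = (
                WeightScheme.hgs() if measure == "hgs" else WeightScheme.wang()
            )
        if measure == "hgs" and scheme.mode is not WeightMode.HGS:
            raise OntologyError("measure 'hgs' requires an HGS weight scheme")
        self.scheme = scheme
        self._ic: ICTable | None = None
        self._pair_cache: dict[tuple[str, str], float] = {}

    @property
    def ic(self) -> ICTable:
        if self._ic is None:
            self._ic = build_ic_table(self.graph)
        return self._ic

    def term_sim(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        if key not in self._pair_cache:
            self._pair_cache[key] = self._compute(*key)
        return self._pair_cache[key]

    def _compute(self, t1: str, t2: str) -> float:
        if self.measure == "resnik":
            return resnik_sim(
                self.graph, self.ic, t1, t2, normalize=self.normalize_resnik
            )
        if self.measure == "relevance":
            return relevance_sim(self.graph, self.ic, t1, t2)
        return graph_term_sim(self.graph, t1, t2, self.scheme)

    def term_sim_matrix(
        self, terms1: Sequence[str], terms2: Sequence[str]
    ) -> np.ndarray:
        out = np.empty((len(terms1), len(terms2)))
        for i, t1 in enumerate(terms1):
            for j, t2 in enumerate(terms2):
                out[i, j] = self.term_sim(t1, t2)
        return out


def term_sim_matrix(
    g1: str,
    g2: str,
    annotations: AnnotationSet,
    engine: SemanticSimilarity,
) -> TermSimMatrix:
    """All term-pair similarities between two genes' annotation sets."""
    rows = tuple(sorted(annotations.terms_of(g1)))
    cols = tuple(sorted(annotations.terms_of(g2)))
    return TermSimMatrix(
        rows=rows, cols=cols, values=engine.term_sim_matrix(rows, cols)
    )


def combine_bma(m: TermSimMatrix | np.ndarray) -> float:
    """Best-match-average: mean of row-wise and column-wise best matches."""
    values = m.values if isinstance(m, TermSimMatrix) else np.asarray(m, dtype=float)
    if values.size == 0:
        raise OntologyError("cannot combine an empty term-pair matrix")
    r, c = values.shape
    return float(
        (values.max(axis=1).sum() + values.max(axis=0).sum()) / (r + c)
    )


def combine_max(m: TermSimMatrix | np.ndarray) -> float:
    """Global maximum entry of the term-pair matrix."""
    values = m.values if isinstance(m, TermSimMatrix) else np.asarray(m, dtype=float)
    if values.size == 0:
        raise OntologyError("cannot combine an empty term-pair matrix")
    return float(values.max())


_COMBINERS = {"bma": combine_bma, "max": combine_max}


@dataclass(frozen=True)
class GeneSimilarityMatrix:
    """Symmetric gene x gene functional similarity matrix.

    Row *i* (similarities of gene *i* to every gene in the set) is gene
    *i*'s feature vector for classification.
    """

    genes: tuple[str, ...]
    values: np.ndarray
    measure: str
    combine: str
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise OntologyError(f"matrix shape {self.values.shape} != ({n}, {n})")

    def index_of(self, gene: str) -> int:
        return self.genes.index(gene)

    def sim(self, g1: str, g2: str) -> float:
        return float(self.values[self.index_of(g1), self.index_of(g2)])

    def feature_matrix(self, *, zero_diagonal: bool = False) -> np.ndarray:
        features = self.values.copy()
        if zero_diagonal:
            np.fill_diagonal(features, 0.0)
        return features

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.genes)

    def to_tsv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.12g")

    @classmethod
    def from_tsv(cls, path: str, measure: str = "unknown", combine: str = "bma"):
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            genes=tuple(str(g) for g in frame.index),
            values=frame.to_numpy(dtype=float),
            measure=measure,
            combine=combine,
        )


def build_gene_matrix(
    genes: Sequence[str],
    annotations: AnnotationSet,
    graph: OntologyGraph | None = None,
    *,
    measure: str = "wang",
    scheme: WeightScheme | None = None,
    combine: str = "bma",
    engine: SemanticSimilarity | None = None,
) -> GeneSimilarityMatrix:
    """Symmetric similarity matrix over ``genes``.

    Each unordered pair is computed once; the diagonal is set to 1.0
    (self-similarity of the normalized measures).  Genes missing from
    ``annotations`` are dropped and reported on the result.
    """
    if combine not in _COMBINERS:
        raise OntologyError(f"unknown combine strategy {combine!r}")
    if engine is None:
        if graph is None:
            raise OntologyError("either a graph or a prepared engine is required")
        engine = SemanticSimilarity(graph, measure=measure, scheme=scheme)
    combiner = _COMBINERS[combine]
    usable = [g for g in genes if g in annotations]
    dropped = tuple(g for g in genes if g not in annotations)
    if dropped:
        logger.info(
            "dropping %d unannotated genes from the matrix: %s",
            len(dropped),
            ", ".join(dropped[:10]),
        )
    if len(usable) < 2:
        raise OntologyError(
            f"need at least 2 annotated genes to build a matrix, got {len(usable)}"
        )
    n = len(usable)
    values = np.eye(n)
    term_lists = {g: tuple(sorted(annotations.terms_of(g))) for g in usable}
    for i in range(n):
        for j in range(i + 1, n):
            block = engine.term_sim_matrix(
                term_lists[usable[i]], term_lists[usable[j]]
            )
            values[i, j] = values[j, i] = combiner(block)
    return GeneSimilarityMatrix(
        genes=tuple(usable),
        values=values,
        measure=engine.measure,
        combine=combine,
        dropped=dropped,
    )
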