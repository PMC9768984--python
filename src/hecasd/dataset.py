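"""Labeled gene sets: SFARI-style tables and synthetic fixtures.

The positive class comes from a SFARI-style gene table.  Evidence
categories 1-2 form the high-confidence genes (HCG) and 3-4 the
low-confidence genes (LCG); categories 5-6, genes without a score, and
syndromic genes outside categories 1-4 are excluded.  Negatives are a
plain list of non-mental-disease gene symbols supplied by the user.

The synthetic generator builds a single-rooted ontology whose branches
are disjoint subtrees, then draws positive genes' annotations mostly
from the first branch and negative genes' mostly from the others, so
the gene similarity matrix has planted block structure whose strength
is set by ``branch_purity``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_similarity import AnnotationSet
from .ontology import Namespace, OntologyGraph, OntologyError, RelationType

__all__ = [
    "SfariRecord",
    "Label",
    "Tier",
    "DatasetVersion",
    "LabeledGeneSet",
    "SyntheticConfig",
    "parse_sfari",
    "select_positive_sets",
    "assemble_dataset",
    "generate_synthetic",
]

DEFAULT_SFARI_COLUMNS = {
    "gene": "gene-symbol",
    "score": "gene-score",
    "syndromic": "syndromic",
}


class Label(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"


class Tier(str, Enum):
    HCG = "HCG"
    LCG = "LCG"
    NEGATIVE = "NEGATIVE"


class DatasetVersion(str, Enum):
    HCG_ONLY = "hcg_only"
    HCG_LCG = "hcg_lcg"


@dataclass(frozen=True)
class SfariRecord:
    gene: str
    score_category: int | None
    syndromic: bool

    def __post_init__(self) -> None:
        if self.score_category is not None and self.score_category not in range(1, 7):
            raise OntologyError(
                f"gene {self.gene!r}: score category {self.score_category} not in 1..6"
            )


@dataclass(frozen=True)
class LabeledGeneSet:
    """Ordered (gene, label, tier) entries with no duplicate genes."""

    entries: tuple[tuple[str, Label, Tier], ...]
    version: DatasetVersion = DatasetVersion.HCG_ONLY

    def __post_init__(self) -> None:
        genes = [g for g, _, _ in self.entries]
        if len(genes) != len(set(genes)):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise OntologyError(f"duplicate genes in labeled set: {dupes}")
        for gene, label, tier in self.entries:
            if (tier is Tier.NEGATIVE) != (label is Label.NEGATIVE):
                raise OntologyError(f"gene {gene!r}: tier {tier} inconsistent with {label}")
            if self.version is DatasetVersion.HCG_ONLY and tier is Tier.LCG:
                raise OntologyError(f"gene {gene!r}: LCG entry in an HCG_ONLY set")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _, _ in self.entries)

    @property
    def labels(self) -> np.ndarray:
        """0/1 vector aligned with :attr:`genes` (1 = positive)."""
        return np.array(
            [1 if label is Label.POSITIVE else 0 for _, label, _ in self.entries],
            dtype=int,
        )

    def positives(self) -> tuple[str, ...]:
        return tuple(g for g, label, _ in self.entries if label is Label.POSITIVE)

    def negatives(self) -> tuple[str, ...]:
        return tuple(g for g, label, _ in self.entries if label is Label.NEGATIVE)

    def restrict(self, genes: Iterable[str]) -> "LabeledGeneSet":
        keep = set(genes)
        return LabeledGeneSet(
            entries=tuple(e for e in self.entries if e[0] in keep),
            version=self.version,
        )

    def to_tsv(self) -> str:
        lines = [
            f"{gene}\t{label.value}\t{tier.value}" for gene, label, tier in self.entries
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(
        cls, source: str | Iterable[str], version: DatasetVersion = DatasetVersion.HCG_ONLY
    ) -> "LabeledGeneSet":
        if isinstance(source, str):
            with open(source, "rt", encoding="utf-8") as handle:
                lines = handle.readlines()
        else:
            lines = list(source)
        entries = []
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, label, tier = line.split("\t")
            entries.append((gene, Label(label), Tier(tier)))
        return cls(entries=tuple(entries), version=version)


def parse_sfari(
    path: str, columns: Mapping[str, str] | None = None
) -> list[SfariRecord]:
    """Read a SFARI-style CSV into records.

    ``columns`` maps the logical fields (``gene``, ``score``,
    ``syndromic``) to the CSV's column names, since those names vary
    across database releases.  Blank scores become ``None``; duplicate
    gene symbols are an error.
    """
    mapping = dict(DEFAULT_SFARI_COLUMNS)
    mapping.update(columns or {})
    frame = pd.read_csv(path, dtype=str)
    missing = [name for name in mapping.values() if name not in frame.columns]
    if missing:
        raise OntologyError(f"SFARI table is missing required columns: {missing}")
    records: list[SfariRecord] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        gene = str(row[mapping["gene"]]).strip()
        if gene in seen:
            raise OntologyError(f"duplicate gene symbol in SFARI table: {gene!r}")
        seen.add(gene)
        raw_score = row[mapping["score"]]
        score = None
        if isinstance(raw_score, str) and raw_score.strip():
            score = int(float(raw_score))
        raw_synd = str(row[mapping["syndromic"]]).strip().lower()
        syndromic = raw_synd in {"1", "true", "yes", "y", "s"}
        records.append(SfariRecord(gene=gene, score_category=score, syndromic=syndromic))
    return records


def select_positive_sets(
    records: Sequence[SfariRecord],
) -> tuple[set[str], set[str], set[str]]:
    """Partition SFARI genes into (HCG, LCG, excluded).

    HCG = categories 1-2, LCG = categories 3-4; everything else
    (categories 5-6 and genes without a score, syndromic or not) is
    excluded.  Syndromic genes in categories 1-4 participate normally.
    """
    hcg, lcg, excluded = set(), set(), set()
    for rec in records:
        if rec.score_category in (1, 2):
            hcg.add(rec.gene)
        elif rec.score_category in (3, 4):
            lcg.add(rec.gene)
        else:
            excluded.add(rec.gene)
    return hcg, lcg, excluded


def assemble_dataset(
    hcg: Iterable[str],
    lcg: Iterable[str],
    negatives: Iterable[str],
    version: DatasetVersion | str = DatasetVersion.HCG_ONLY,
) -> LabeledGeneSet:
    """Combine positive tiers with the negative list into one labeled set."""
    version = DatasetVersion(version)
    hcg, lcg, negatives = set(hcg), set(lcg), set(negatives)
    positives = hcg | (lcg if version is DatasetVersion.HCG_LCG else set())
    overlap = sorted(positives & negatives)
    if overlap:
        raise OntologyError(f"genes appear on both sides: {overlap}")
    if not positives or not negatives:
        raise OntologyError("both a positive and a negative gene set are required")
    entries: list[tuple[str, Label, Tier]] = []
    for gene in sorted(hcg):
        entries.append((gene, Label.POSITIVE, Tier.HCG))
    if version is DatasetVersion.HCG_LCG:
        for gene in sorted(lcg - hcg):
            entries.append((gene, Label.POSITIVE, Tier.LCG))
    for gene in sorted(negatives):
        entries.append((gene, Label.NEGATIVE, Tier.NEGATIVE))
    return LabeledGeneSet(entries=tuple(entries), version=version)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the planted-structure generator.

    ``branch_purity`` is the probability that each of a gene's terms is
    drawn from its own class's branch (branch 1 for positives, the
    remaining branches for negatives) rather than uniformly from the
    whole ontology; it must exceed 0.5 so the classes are learnable.
    """

    n_terms_per_branch: int = 30
    n_branches: int = 2
    depth: int = 5
    part_of_fraction: float = 0.2
    n_pos_genes: int = 100
    n_neg_genes: int = 100
    terms_per_gene: tuple[int, int] = (2, 15)
    branch_purity: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_terms_per_branch": self.n_terms_per_branch,
            "n_branches": self.n_branches,
            "depth": self.depth,
            "n_pos_genes": self.n_pos_genes,
            "n_neg_genes": self.n_neg_genes,
        }
        for label, value in counts.items():
            if value < 1:
                raise OntologyError(f"{label} must be positive, got {value}")
        if self.n_branches < 2:
            raise OntologyError("need at least 2 branches for two gene classes")
        if self.depth < 2:
            raise OntologyError("branch depth must be at least 2")
        if not 0.0 <= self.part_of_fraction <= 1.0:
            raise OntologyError("part_of_fraction must lie in [0, 1]")
        lo, hi = self.terms_per_gene
        if not 1 <= lo <= hi:
            raise OntologyError(f"bad terms_per_gene range ({lo}, {hi})")
        if hi > self.n_terms_per_branch:
            raise OntologyError(
                f"terms_per_gene max {hi} exceeds branch size {self.n_terms_per_branch}"
            )
        if not 0.5 < self.branch_purity <= 1.0:
            raise OntologyError(
                f"branch_purity must lie in (0.5, 1], got {self.branch_purity}"
            )


def _sample_relation(rng: np.random.Generator, part_of_fraction: float) -> RelationType:
    return (
        RelationType.PART_OF
        if rng.random() < part_of_fraction
        else RelationType.IS_A
    )


def generate_synthetic(
    config: SyntheticConfig,
) -> tuple[OntologyGraph, AnnotationSet, LabeledGeneSet]:
    """Ontology + annotations + labels with planted class structure.

    The ontology is a single root with ``n_branches`` subtrees; within a
    branch each new term attaches to a uniformly chosen earlier term of
    depth < ``depth`` (occasionally gaining a second parent, making the
    branch a proper DAG).  Edge relations are part-of with probability
    ``part_of_fraction``.  Everything is reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    root = "T:ROOT"
    edges: list[tuple[str, str, RelationType]] = []
    branch_terms: list[list[str]] = []
    for b in range(1, config.n_branches + 1):
        members: list[str] = []
        depth_of: dict[str, int] = {}
        for i in range(config.n_terms_per_branch):
            term = f"T:B{b:02d}N{i:03d}"
            if i == 0:
                edges.append((term, root, _sample_relation(rng, config.part_of_fraction)))
                depth_of[term] = 1
            else:
                candidates = [t for t in members if depth_of[t] < config.depth]
                parent = candidates[rng.integers(len(candidates))]
                edges.append((term, parent, _sample_relation(rng, config.part_of_fraction)))
                depth_of[term] = depth_of[parent] + 1
                # occasional second parent keeps the branch a DAG, not a tree
                if len(members) > 1 and rng.random() < 0.2:
                    others = [t for t in candidates if t != parent]
                    if others:
                        second = others[rng.integers(len(others))]
                        edges.append(
                            (term, second, _sample_relation(rng, config.part_of_fraction))
                        )
                        depth_of[term] = max(depth_of[term], depth_of[second] + 1)
            members.append(term)
        branch_terms.append(members)
    terms = {root: Namespace.BP}
    for members in branch_terms:
        terms.update({t: Namespace.BP for t in members})
    graph = OntologyGraph(terms, edges)

    all_terms = [t for members in branch_terms for t in members]
    pos_pool = branch_terms[0]
    neg_pool = [t for members in branch_terms[1:] for t in members]
    lo, hi = config.terms_per_gene

    def draw_gene(own_pool: list[str]) -> frozenset[str]:
        k = int(rng.integers(lo, hi + 1))
        chosen: set[str] = set()
        while len(chosen) < k:
            pool = own_pool if rng.random() < config.branch_purity else all_terms
            chosen.add(pool[rng.integers(len(pool))])
        return frozenset(chosen)

    annotations: dict[str, frozenset[str]] = {}
    entries: list[tuple[str, Label, Tier]] = []
    for i in range(config.n_pos_genes):
        gene = f"POS_{i:04d}"
        annotations[gene] = draw_gene(pos_pool)
        entries.append((gene, Label.POSITIVE, Tier.HCG))
    for i in range(config.n_neg_genes):
        gene = f"NEG_{i:04d}"
        annotations[gene] = draw_gene(neg_pool)
        entries.append((gene, Label.NEGATIVE, Tier.NEGATIVE))
    annotation_set = AnnotationSet(annotations=annotations)
    labeled = LabeledGeneSet(entries=tuple(entries), version=DatasetVersion.HCG_ONLY)
    return graph, annotation_set, labeled
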