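"""Functional / non-functional isoform-pair gold standard construction.

Positive pairs: two *single-isoform* genes co-annotated to the same retained
ontology term or pathway, or linked by a retained protein-protein
interaction; the pair of their single isoforms is labelled functional.

Negative pairs: a gene carrying a NOT-qualified annotation for a term is
declared unrelated to every gene positively annotated to that term; all
isoforms of both genes participate (the NOT side is not restricted to
single-isoform genes).

Processing order: evidence-code filtering, true-path (upward) propagation of
positive annotations, inverse (downward) propagation of NOT annotations,
then removal of terms annotated to fewer than 10 or more than 1000 genes.
Pairs found in both sets are resolved in favour of the positive label, since
sharing even one biological process makes a pair functional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from .catalog import GeneCatalog
from .exceptions import InputError
from .pair_features import canonical_pair

EXCLUDED_EVIDENCE_CODES = frozenset({"IEA", "NAS", "ND"})
TERM_SIZE_MIN = 10
TERM_SIZE_MAX = 1000
MENTHA_MIN_SCORE = 0.2
APID_MIN_EVIDENCE = 2
PPI_SOURCES = frozenset({"intact", "biogrid", "apid", "iid", "mentha"})


class OntologyDAG:
    """Directed acyclic term graph with child -> parent edges."""

    def __init__(self, edges: Iterable[tuple[str, str]], terms: Iterable[str] = ()):
        self.graph = nx.DiGraph()
        self.graph.add_nodes_from(terms)
        self.graph.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise InputError(f"ontology contains a cycle through {cycle[0][0]!r}")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable by following child -> parent edges."""
        if term not in self.graph:
            return set()
        return nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        if term not in self.graph:
            return set()
        return nx.ancestors(self.graph, term)

    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene-to-term (or pathway / interaction) assignment."""

    gene_id: str
    term_id: str
    qualifier: str = "positive"  # "positive" or "NOT"
    evidence_code: str = "EXP"
    source: str = "ontology"  # "ontology", "pathway" or "ppi"

    def __post_init__(self) -> None:
        if self.qualifier not in ("positive", "NOT"):
            raise InputError(f"unknown qualifier: {self.qualifier!r}")
        if self.qualifier == "NOT" and self.source != "ontology":
            raise InputError("NOT qualifier is only valid for ontology records")


@dataclass(frozen=True)
class PPIRecord:
    gene_a: str
    gene_b: str
    source: str
    evidence_count: int = 1
    score: float = 1.0
    orthology_only: bool = False
    taxon_a: str = "mouse"
    taxon_b: str = "mouse"


@dataclass(frozen=True)
class LabeledPair:
    isoform_a: str
    isoform_b: str
    label: int  # 1 functional, 0 non-functional
    provenance: frozenset[tuple[str, str]] = frozenset()

    @property
    def key(self) -> tuple[str, str]:
        return (self.isoform_a, self.isoform_b)


def filter_evidence(
    annotations: Iterable[AnnotationRecord],
    excluded: frozenset[str] = EXCLUDED_EVIDENCE_CODES,
) -> list[AnnotationRecord]:
    """Drop ontology records with excluded evidence codes; keep the rest."""
    return [
        a
        for a in annotations
        if a.source != "ontology" or a.evidence_code not in excluded
    ]


def _to_gene_terms(
    annotations: Iterable[AnnotationRecord], qualifier: str
) -> dict[str, set[str]]:
    gene_terms: dict[str, set[str]] = {}
    for a in annotations:
        if a.source == "ontology" and a.qualifier == qualifier:
            gene_terms.setdefault(a.gene_id, set()).add(a.term_id)
    return gene_terms


def propagate_true_path(
    dag: OntologyDAG, annotations: Iterable[AnnotationRecord]
) -> list[AnnotationRecord]:
    """Extend each positive ontology annotation to all ancestor terms."""
    annotations = list(annotations)
    result = list(annotations)
    seen = {
        (a.gene_id, a.term_id)
        for a in annotations
        if a.source == "ontology" and a.qualifier == "positive"
    }
    for a in annotations:
        if a.source != "ontology" or a.qualifier != "positive":
            continue
        for anc in sorted(dag.ancestors(a.term_id)):
            if (a.gene_id, anc) not in seen:
                seen.add((a.gene_id, anc))
                result.append(
                    AnnotationRecord(
                        a.gene_id, anc, "positive", a.evidence_code, "ontology"
                    )
                )
    return result


def propagate_not_inverse(
    dag: OntologyDAG, annotations: Iterable[AnnotationRecord]
) -> list[AnnotationRecord]:
    """Extend each NOT annotation to all descendant terms."""
    annotations = list(annotations)
    result = list(annotations)
    seen = {(a.gene_id, a.term_id) for a in annotations if a.qualifier == "NOT"}
    for a in annotations:
        if a.qualifier != "NOT":
            continue
        for desc in sorted(dag.descendants(a.term_id)):
            if (a.gene_id, desc) not in seen:
                seen.add((a.gene_id, desc))
                result.append(
                    AnnotationRecord(
                        a.gene_id, desc, "NOT", a.evidence_code, "ontology"
                    )
                )
    return result


def term_gene_sets(
    annotations: Iterable[AnnotationRecord], qualifier: str = "positive"
) -> dict[str, set[str]]:
    """term -> set of genes with the given qualifier (ontology source only)."""
    sets: dict[str, set[str]] = {}
    for a in annotations:
        if a.source == "ontology" and a.qualifier == qualifier:
            sets.setdefault(a.term_id, set()).add(a.gene_id)
    return sets


def filter_terms(
    sets: Mapping[str, set[str]],
    min_size: int = TERM_SIZE_MIN,
    max_size: int = TERM_SIZE_MAX,
) -> dict[str, set[str]]:
    """Keep terms whose gene count is within [min_size, max_size]."""
    return {
        t: set(genes)
        for t, genes in sets.items()
        if min_size <= len(genes) <= max_size
    }


def pathway_gene_sets(
    annotations: Iterable[AnnotationRecord],
) -> dict[str, set[str]]:
    """pathway -> gene sets; flat memberships, no propagation or filtering."""
    sets: dict[str, set[str]] = {}
    for a in annotations:
        if a.source == "pathway":
            sets.setdefault(a.term_id, set()).add(a.gene_id)
    return sets


def filter_ppi(
    records: Iterable[PPIRecord], target_taxon: str = "mouse"
) -> set[tuple[str, str]]:
    """Source-specific quality filtering; returns retained gene pairs."""
    kept: set[tuple[str, str]] = set()
    for r in records:
        source = r.source.lower()
        if source not in PPI_SOURCES:
            raise InputError(f"unknown PPI source: {r.source!r}")
        if r.taxon_a != target_taxon or r.taxon_b != target_taxon:
            continue
        if source == "apid" and r.evidence_count < APID_MIN_EVIDENCE:
            continue
        if source == "iid" and r.orthology_only:
            continue
        if source == "mentha" and r.score < MENTHA_MIN_SCORE:
            continue
        if r.gene_a == r.gene_b:
            continue
        kept.add(canonical_pair(r.gene_a, r.gene_b))
    return kept


def build_positive_pairs(
    catalog: GeneCatalog,
    term_sets: Mapping[str, set[str]],
    pathway_sets: Mapping[str, set[str]] | None = None,
    ppi_pairs: Iterable[tuple[str, str]] = (),
) -> dict[tuple[str, str], set[tuple[str, str]]]:
    """Positive pairs: single-isoform genes co-annotated or interacting.

    Returns canonical isoform-pair -> provenance set of (source, id).
    """
    single = set(catalog.single_isoform_genes())
    iso_of = {g: catalog.isoforms_of(g)[0] for g in single}
    positives: dict[tuple[str, str], set[tuple[str, str]]] = {}

    def add(g1: str, g2: str, source: str, ident: str) -> None:
        if g1 == g2 or g1 not in single or g2 not in single:
            return
        pair = canonical_pair(iso_of[g1], iso_of[g2])
        positives.setdefault(pair, set()).add((source, ident))

    for source, sets in (
        ("ontology", term_sets),
        ("pathway", pathway_sets or {}),
    ):
        for ident, genes in sets.items():
            eligible = sorted(genes & single)
            for i, g1 in enumerate(eligible):
                for g2 in eligible[i + 1:]:
                    add(g1, g2, source, ident)
    for g1, g2 in ppi_pairs:
        add(g1, g2, "ppi", f"{g1}-{g2}")
    return positives


def build_negative_pairs(
    catalog: GeneCatalog,
    not_term_sets: Mapping[str, set[str]],
    positive_term_sets: Mapping[str, set[str]],
) -> dict[tuple[str, str], set[tuple[str, str]]]:
    """Negative pairs from NOT annotations against co-annotated genes.

    For each term present in both mappings, every isoform of each
    NOT-annotated gene is paired with every isoform of each positively
    annotated gene. Multi-isoform genes participate on both sides; same-gene
    pairs are never emitted.
    """
    negatives: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for term, not_genes in not_term_sets.items():
        pos_genes = positive_term_sets.get(term)
        if not pos_genes:
            continue
        for ng in sorted(not_genes):
            if ng not in catalog.gene_ids:
                continue
            for pg in sorted(pos_genes - {ng}):
                if pg not in catalog.gene_ids:
                    continue
                for iso_n in catalog.isoforms_of(ng):
                    for iso_p in catalog.isoforms_of(pg):
                        pair = canonical_pair(iso_n, iso_p)
                        negatives.setdefault(pair, set()).add(("ontology", term))
    return negatives


def resolve_conflicts(
    positives: Mapping[tuple[str, str], set[tuple[str, str]]],
    negatives: Mapping[tuple[str, str], set[tuple[str, str]]],
) -> tuple[list[LabeledPair], list[LabeledPair]]:
    """Make the two sets disjoint: a pair in both stays positive only."""
    pos = [
        LabeledPair(a, b, 1, frozenset(prov))
        for (a, b), prov in sorted(positives.items())
    ]
    neg = [
        LabeledPair(a, b, 0, frozenset(prov))
        for (a, b), prov in sorted(negatives.items())
        if (a, b) not in positives
    ]
    return pos, neg


@dataclass
class LabelSets:
    """The three-way partition: positives, negatives, everything else unknown."""

    positives: list[LabeledPair]
    negatives: list[LabeledPair] = field(default_factory=list)

    def summary(self) -> dict[str, int]:
        return {
            "positive_pairs": len(self.positives),
            "negative_pairs": len(self.negatives),
        }


def build_label_sets(
    catalog: GeneCatalog,
    dag: OntologyDAG,
    annotations: Iterable[AnnotationRecord],
    ppi_records: Iterable[PPIRecord] = (),
    target_taxon: str = "mouse",
) -> LabelSets:
    """End-to-end label construction with the canonical processing order."""
    annotations = filter_evidence(list(annotations))
    annotations = propagate_true_path(dag, annotations)
    annotations = propagate_not_inverse(dag, annotations)
    pos_sets = filter_terms(term_gene_sets(annotations, "positive"))
    not_sets_all = term_gene_sets(annotations, "NOT")
    # uniform term retention: negatives restricted to size-filtered terms
    not_sets = {t: g for t, g in not_sets_all.items() if t in pos_sets}
    pathways = pathway_gene_sets(annotations)
    ppi_pairs = filter_ppi(list(ppi_records), target_taxon=target_taxon)
    positives = build_positive_pairs(catalog, pos_sets, pathways, ppi_pairs)
    negatives = build_negative_pairs(catalog, not_sets, pos_sets)
    pos, neg = resolve_conflicts(positives, negatives)
    return LabelSets(positives=pos, negatives=neg)
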