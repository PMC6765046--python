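"""Readers and writers for every on-disk format the pipeline touches.

Formats: FASTA (sequences, via Biopython), an OBO dialect (ontology terms
with is_a / part_of relations, via obonet), a GAF dialect (tab-separated
annotations with NOT qualifiers and evidence codes; both a headered
4-column form and the headerless 17-column layout are accepted), and TSV
tables for expression, sample -> tissue maps, isoform -> gene maps, pathway
membership, PPI edges and predicted edge lists.

All readers validate and raise :class:`InputError` with the offending
column, id or cycle member; writer/reader pairs are inverse on valid data.
mRNA sequences are uppercased and U is normalized to T on read so the k-mer
alphabet is always {A, C, G, T}.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import obonet
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .catalog import FilterReport, GeneCatalog, IsoformRecord, filter_records
from .exceptions import InputError
from .expression import ExpressionMatrix
from .labels import AnnotationRecord, OntologyDAG, PPIRecord
from .tissue_networks import TissueEdge

DEFAULT_OBO_RELATIONS = frozenset({"is_a", "part_of"})


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path, normalize_rna: bool = False) -> dict[str, str]:
    """id -> uppercased sequence; U -> T when ``normalize_rna`` is set."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise InputError(f"duplicate FASTA id: {record.id}")
        seq = str(record.seq).strip().upper()
        if not seq:
            raise InputError(f"empty FASTA record: {record.id}")
        if normalize_rna:
            seq = seq.replace("U", "T")
        sequences[record.id] = seq
    return sequences


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------- ontology

def read_ontology(
    path: str | Path, relations: frozenset[str] = DEFAULT_OBO_RELATIONS
) -> OntologyDAG:
    """Parse an OBO file into a child -> parent DAG over the given relations."""
    graph = obonet.read_obo(str(path))
    edges = [
        (child, parent)
        for child, parent, key in graph.edges(keys=True)
        if key in relations
    ]
    return OntologyDAG(edges, terms=list(graph.nodes))


def write_ontology(
    path: str | Path, edges: Sequence[tuple[str, str, str]], terms: Iterable[str]
) -> None:
    """Write a minimal OBO dialect: [Term] stanzas with is_a / relationship."""
    by_child: dict[str, list[tuple[str, str]]] = {}
    for child, parent, relation in edges:
        by_child.setdefault(child, []).append((parent, relation))
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in terms:
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            for parent, relation in by_child.get(term, []):
                if relation == "is_a":
                    fh.write(f"is_a: {parent} ! {parent}\n")
                else:
                    fh.write(f"relationship: {relation} {parent} ! {parent}\n")
            fh.write("\n")


# ---------------------------------------------------------------- GAF dialect

_GAF_MIN_COLUMNS = ("gene_id", "qualifier", "term_id", "evidence_code")


def _parse_qualifier(raw: str) -> str:
    tokens = [t.strip() for t in raw.split("|")]
    return "NOT" if "NOT" in tokens else "positive"


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read GAF-dialect annotations.

    Lines starting with '!' are comments. A header row naming at least
    gene_id, qualifier, term_id and evidence_code selects the headered
    dialect (extra columns ignored); otherwise rows are treated as standard
    17-column GAF (columns 2, 4, 5, 7).
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            rows.append(line.split("\t"))
    if not rows:
        return []
    records: list[AnnotationRecord] = []
    header = rows[0]
    if "gene_id" in header:
        missing = [c for c in _GAF_MIN_COLUMNS if c not in header]
        if missing:
            raise InputError(f"annotation file missing columns: {missing}")
        idx = {c: header.index(c) for c in _GAF_MIN_COLUMNS}
        source_idx = header.index("source") if "source" in header else None
        for row in rows[1:]:
            source = row[source_idx] if source_idx is not None else "ontology"
            records.append(
                AnnotationRecord(
                    gene_id=row[idx["gene_id"]],
                    term_id=row[idx["term_id"]],
                    qualifier=_parse_qualifier(row[idx["qualifier"]]),
                    evidence_code=row[idx["evidence_code"]],
                    source=source,
                )
            )
    else:
        for row in rows:
            if len(row) < 7:
                raise InputError(
                    "GAF row has fewer than 7 columns and no header names "
                    f"{list(_GAF_MIN_COLUMNS)}"
                )
            records.append(
                AnnotationRecord(
                    gene_id=row[1],
                    term_id=row[4],
                    qualifier=_parse_qualifier(row[3]),
                    evidence_code=row[6],
                    source="ontology",
                )
            )
    return records


def write_annotations(path: str | Path, records: Iterable[AnnotationRecord]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow([*_GAF_MIN_COLUMNS, "source"])
        for r in records:
            qualifier = "NOT" if r.qualifier == "NOT" else ""
            writer.writerow(
                [r.gene_id, qualifier, r.term_id, r.evidence_code, r.source]
            )


# ---------------------------------------------------------------- TSV tables

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise InputError(f"{Path(path).name}: missing required columns {missing}")
    return table


def read_expression(
    path: str | Path, tissue_map_path: str | Path
) -> ExpressionMatrix:
    """Expression TSV (isoform_id + one column per sample) + tissue map."""
    table = pd.read_csv(path, sep="\t")
    if "isoform_id" not in table.columns:
        raise InputError("expression table missing required column 'isoform_id'")
    table = table.set_index("isoform_id")
    tissue_map = _read_tsv(tissue_map_path, ["sample_id", "tissue"])
    mapping = dict(zip(tissue_map["sample_id"], tissue_map["tissue"]))
    unmapped = [s for s in table.columns if s not in mapping]
    if unmapped:
        raise InputError(f"samples absent from tissue map: {unmapped}")
    return ExpressionMatrix(values=table.astype(float), sample_tissue=mapping)


def write_expression(
    path: str | Path, tissue_map_path: str | Path, matrix: ExpressionMatrix
) -> None:
    out = matrix.values.copy()
    out.insert(0, "isoform_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")
    pd.DataFrame(
        {
            "sample_id": list(matrix.values.columns),
            "tissue": [matrix.sample_tissue[s] for s in matrix.values.columns],
        }
    ).to_csv(tissue_map_path, sep="\t", index=False)


def read_isoform_gene_map(path: str | Path) -> dict[str, str]:
    table = _read_tsv(path, ["isoform_id", "gene_id"])
    if table["isoform_id"].duplicated().any():
        dupes = table.loc[table["isoform_id"].duplicated(), "isoform_id"]
        raise InputError(f"duplicate isoform ids in map: {list(dupes)[:5]}")
    return dict(zip(table["isoform_id"], table["gene_id"]))


def write_isoform_gene_map(path: str | Path, catalog: GeneCatalog) -> None:
    pd.DataFrame(
        {
            "isoform_id": catalog.isoform_ids,
            "gene_id": [catalog.gene_of(i) for i in catalog.isoform_ids],
        }
    ).to_csv(path, sep="\t", index=False)


def read_pathways(path: str | Path) -> list[AnnotationRecord]:
    table = _read_tsv(path, ["pathway_id", "gene_id"])
    return [
        AnnotationRecord(
            gene_id=row.gene_id, term_id=row.pathway_id,
            qualifier="positive", evidence_code="NA", source="pathway",
        )
        for row in table.itertuples()
    ]


def write_pathways(path: str | Path, records: Iterable[AnnotationRecord]) -> None:
    pd.DataFrame(
        [(r.term_id, r.gene_id) for r in records],
        columns=["pathway_id", "gene_id"],
    ).to_csv(path, sep="\t", index=False)


_PPI_COLUMNS = (
    "gene_a", "gene_b", "source", "evidence_count", "score",
    "orthology_flag", "taxon_a", "taxon_b",
)


def read_ppi(path: str | Path) -> list[PPIRecord]:
    table = _read_tsv(path, _PPI_COLUMNS)
    return [
        PPIRecord(
            gene_a=row.gene_a,
            gene_b=row.gene_b,
            source=row.source,
            evidence_count=int(row.evidence_count),
            score=float(row.score),
            orthology_only=row.orthology_flag in ("1", "true", "True"),
            taxon_a=row.taxon_a,
            taxon_b=row.taxon_b,
        )
        for row in table.itertuples()
    ]


def write_ppi(path: str | Path, records: Iterable[PPIRecord]) -> None:
    pd.DataFrame(
        [
            (
                r.gene_a, r.gene_b, r.source, r.evidence_count, r.score,
                int(r.orthology_only), r.taxon_a, r.taxon_b,
            )
            for r in records
        ],
        columns=list(_PPI_COLUMNS),
    ).to_csv(path, sep="\t", index=False)


_EDGE_COLUMNS = (
    "isoform_a", "isoform_b", "prob_full", "prob_ablated", "tissue", "loto_class"
)


def write_edge_list(path: str | Path, edges: Iterable[TissueEdge]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_EDGE_COLUMNS)
        for e in edges:
            writer.writerow(
                [
                    e.isoform_a, e.isoform_b,
                    f"{e.prob_full:.6f}", f"{e.prob_ablated:.6f}",
                    e.tissue, e.loto_class,
                ]
            )


def read_edge_list(path: str | Path) -> list[TissueEdge]:
    table = _read_tsv(path, _EDGE_COLUMNS)
    return [
        TissueEdge(
            isoform_a=row.isoform_a,
            isoform_b=row.isoform_b,
            tissue="" if pd.isna(row.tissue) else row.tissue,
            prob_full=float(row.prob_full),
            prob_ablated=float(row.prob_ablated),
            loto_class=row.loto_class,
        )
        for row in table.itertuples()
    ]


# ---------------------------------------------------------------- catalog

def load_catalog(
    mrna_fasta: str | Path,
    protein_fasta: str | Path,
    map_path: str | Path,
) -> tuple[GeneCatalog, FilterReport]:
    """Assemble a catalog from two FASTA files and an isoform -> gene map.

    Isoforms missing either sequence, shorter than 30 residues, or carrying
    non-standard characters are dropped; the report records each reason.
    """
    mrna = read_fasta(mrna_fasta, normalize_rna=True)
    protein = read_fasta(protein_fasta)
    mapping = read_isoform_gene_map(map_path)
    report = FilterReport()
    candidates: list[IsoformRecord] = []
    for isoform_id, gene_id in mapping.items():
        if isoform_id not in mrna:
            report.add(isoform_id, "missing mRNA sequence")
            continue
        if isoform_id not in protein:
            report.add(isoform_id, "missing protein sequence")
            continue
        candidates.append(
            IsoformRecord(isoform_id, gene_id, mrna[isoform_id], protein[isoform_id])
        )
    kept, seq_report = filter_records(candidates)
    report.dropped.update(seq_report.dropped)
    return GeneCatalog(kept), report


def write_catalog(
    mrna_fasta: str | Path,
    protein_fasta: str | Path,
    map_path: str | Path,
    catalog: GeneCatalog,
) -> None:
    write_fasta(mrna_fasta, {r.isoform_id: r.mrna_sequence for r in catalog})
    write_fasta(protein_fasta, {r.isoform_id: r.protein_sequence for r in catalog})
    write_isoform_gene_map(map_path, catalog)
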