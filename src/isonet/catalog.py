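"""Isoform catalog: the identity layer of the pipeline.

A :class:`GeneCatalog` holds one :class:`IsoformRecord` per mRNA isoform,
each carrying the parent gene, the mRNA sequence and the protein sequence.
Records are filtered on construction: proteins shorter than 30 residues or
sequences containing non-standard characters are rejected (see
:func:`filter_records`), mirroring the preprocessing applied to genome
annotations before feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .exceptions import InputError

MRNA_ALPHABET = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
MIN_PROTEIN_LENGTH = 30

_MRNA_SET = frozenset(MRNA_ALPHABET)
_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class IsoformRecord:
    """One mRNA isoform with its parent gene and both sequences."""

    isoform_id: str
    gene_id: str
    mrna_sequence: str
    protein_sequence: str


@dataclass
class FilterReport:
    """Why each rejected isoform was dropped at load time."""

    dropped: dict[str, str] = field(default_factory=dict)

    def add(self, isoform_id: str, reason: str) -> None:
        self.dropped[isoform_id] = reason

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.dropped)


def validate_record(record: IsoformRecord) -> str | None:
    """Return a rejection reason for *record*, or None if it passes."""
    if len(record.protein_sequence) < MIN_PROTEIN_LENGTH:
        return f"protein shorter than {MIN_PROTEIN_LENGTH} amino acids"
    if not set(record.protein_sequence) <= _AA_SET:
        bad = sorted(set(record.protein_sequence) - _AA_SET)
        return f"non-standard protein characters: {''.join(bad)}"
    if not record.mrna_sequence:
        return "empty mRNA sequence"
    if not set(record.mrna_sequence) <= _MRNA_SET:
        bad = sorted(set(record.mrna_sequence) - _MRNA_SET)
        return f"non-standard mRNA characters: {''.join(bad)}"
    return None


def filter_records(
    records: Iterable[IsoformRecord],
) -> tuple[list[IsoformRecord], FilterReport]:
    """Split records into (kept, report-of-dropped) using the load-time rules."""
    kept: list[IsoformRecord] = []
    report = FilterReport()
    for record in records:
        reason = validate_record(record)
        if reason is None:
            kept.append(record)
        else:
            report.add(record.isoform_id, reason)
    return kept, report


class GeneCatalog:
    """Immutable collection of isoform records with a gene -> isoforms index.

    Isoform ids must be unique and each isoform maps to exactly one gene.
    Iteration order is by isoform id, which makes every downstream pair
    enumeration deterministic.
    """

    def __init__(self, records: Iterable[IsoformRecord]):
        self._records: dict[str, IsoformRecord] = {}
        self._gene_to_isoforms: dict[str, list[str]] = {}
        for record in records:
            if record.isoform_id in self._records:
                raise InputError(f"duplicate isoform id: {record.isoform_id}")
            self._records[record.isoform_id] = record
        for isoform_id in sorted(self._records):
            record = self._records[isoform_id]
            self._gene_to_isoforms.setdefault(record.gene_id, []).append(isoform_id)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, isoform_id: str) -> bool:
        return isoform_id in self._records

    def __iter__(self) -> Iterator[IsoformRecord]:
        for isoform_id in sorted(self._records):
            yield self._records[isoform_id]

    def __getitem__(self, isoform_id: str) -> IsoformRecord:
        try:
            return self._records[isoform_id]
        except KeyError:
            raise InputError(f"unknown isoform id: {isoform_id}") from None

    @property
    def isoform_ids(self) -> list[str]:
        return sorted(self._records)

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self._gene_to_isoforms)

    def isoforms_of(self, gene_id: str) -> list[str]:
        try:
            return list(self._gene_to_isoforms[gene_id])
        except KeyError:
            raise InputError(f"unknown gene id: {gene_id}") from None

    def gene_of(self, isoform_id: str) -> str:
        return self[isoform_id].gene_id

    def single_isoform_genes(self) -> list[str]:
        """Genes producing exactly one mRNA isoform (the positive-label universe)."""
        return sorted(
            g for g, isos in self._gene_to_isoforms.items() if len(isos) == 1
        )

    def n_genes(self) -> int:
        return len(self._gene_to_isoforms)
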