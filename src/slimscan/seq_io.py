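"""Readers and writers for the pipeline's external formats.

Protein databases travel as plain FASTA; per-protein metadata (gene
symbol, taxonomic category, GO terms) as a tab-separated annotation
table; every analysis stage emits a TSV. All coordinates written to
outputs are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import ALPHABET

logger = logging.getLogger(__name__)

#: Ambiguity/rare codes collapsed to X (B=D/N, Z=E/Q, U=selenocysteine,
#: O=pyrrolysine); X scores as the BLOSUM50 X row downstream.
_AMBIGUOUS = {"B": "X", "Z": "X", "U": "X", "O": "X"}

GO_NAMESPACES = ("MF", "BP")

__all__ = [
    "ProteinRecord",
    "AnnotationTable",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "write_table",
]


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass(frozen=True)
class ProteinRecord:
    """One database entry: accession, free-text description, residues."""

    accession: str
    sequence: str
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"{self.accession}: illegal residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotationTable:
    """Per-accession gene symbol, taxon category and GO term set.

    GO terms are ``(term_id, namespace)`` pairs with namespace MF
    (molecular function) or BP (biological process).
    """

    rows: dict[str, dict] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, accession: str) -> bool:
        return accession in self.rows

    def add(self, accession, gene_symbol, taxon_category, go_terms):
        if accession in self.rows:
            raise ValueError(f"duplicate accession: {accession}")
        go_terms = frozenset(go_terms)
        for term, ns in go_terms:
            if ns not in GO_NAMESPACES:
                raise ValueError(
                    f"{accession}: unknown GO namespace {ns!r} for {term}"
                )
        self.rows[accession] = {
            "gene_symbol": gene_symbol,
            "taxon_category": taxon_category,
            "go_terms": go_terms,
        }

    def gene_symbol(self, accession: str) -> str:
        return self.rows[accession]["gene_symbol"]

    def taxon_category(self, accession: str) -> str:
        return self.rows[accession]["taxon_category"]

    def go_terms(self, accession: str) -> frozenset:
        return self.rows[accession]["go_terms"]


def read_fasta(path) -> list[ProteinRecord]:
    """Parse a protein FASTA file into ordered ProteinRecords.

    Sequences are uppercased; B/Z/U/O are mapped to X with a warning.
    Any other residue outside the 20-letter alphabet (plus X) raises a
    ParseError naming the line it occurs on.
    """
    path = Path(path)
    records = []
    mapped = False
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if not rec.id:
                raise ParseError(f"{path}: record with empty header")
            seq = str(rec.seq).upper()
            cleaned = "".join(_AMBIGUOUS.get(c, c) for c in seq)
            if cleaned != seq:
                mapped = True
            bad = set(cleaned) - set(ALPHABET)
            if bad:
                raise ParseError(
                    f"{path}: illegal residue(s) {sorted(bad)} in record "
                    f"{rec.id!r} near line {_find_line(path, rec.id)}"
                )
            if not cleaned:
                raise ParseError(
                    f"{path}: empty sequence for record {rec.id!r} near "
                    f"line {_find_line(path, rec.id)}"
                )
            records.append(
                ProteinRecord(rec.id, cleaned, rec.description[len(rec.id):].strip())
            )
    if mapped:
        logger.warning("%s: ambiguity codes B/Z/U/O mapped to X", path)
    return records


def _find_line(path: Path, accession: str) -> int:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">") and line[1:].split()[:1] == [accession]:
                return lineno
    return 0


def write_fasta(records, path, width: int = 60) -> None:
    """Write ProteinRecords as FASTA (fixed line width, order preserved)."""
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(Path(path), wrap=width)
    writer.write_file(seqs)


def read_annotations(path) -> AnnotationTable:
    """Read the annotation TSV (accession, gene_symbol, taxon_category,
    go_terms with semicolon-joined ``GO:nnnnnnn:NS`` entries).

    ``#`` comment lines are ignored; an empty go_terms cell is allowed.
    Duplicate accessions or unknown namespaces raise ValueError.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    required = ["accession", "gene_symbol", "taxon_category", "go_terms"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    table = AnnotationTable()
    for row in df.itertuples(index=False):
        terms = []
        if row.go_terms:
            for item in row.go_terms.split(";"):
                item = item.strip()
                if not item:
                    continue
                term, _, ns = item.rpartition(":")
                if not term:
                    raise ParseError(
                        f"{path}: malformed GO entry {item!r} for "
                        f"{row.accession}"
                    )
                terms.append((term, ns))
        table.add(row.accession, row.gene_symbol, row.taxon_category, terms)
    return table


def write_annotations(table: AnnotationTable, path) -> None:
    rows = [
        {
            "accession": acc,
            "gene_symbol": r["gene_symbol"],
            "taxon_category": r["taxon_category"],
            "go_terms": ";".join(
                f"{t}:{ns}" for t, ns in sorted(r["go_terms"])
            ),
        }
        for acc, r in table.rows.items()
    ]
    write_table(rows, path, ["accession", "gene_symbol", "taxon_category", "go_terms"])


def write_table(rows, path, schema) -> None:
    """Write dict-rows as a TSV with a fixed column order.

    Floats are rendered with 6 significant digits, so small E-values
    come out in scientific notation (e.g. ``3.9e-11``). Empty input
    yields a header-only file.
    """
    df = pd.DataFrame(list(rows), columns=list(schema))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
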