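"""Database scanning for query-like short linear motifs.

A scan aligns the query peptide glocally against every database record
(one best alignment per record), keeps hits passing both an E-value and
an identity-degree threshold, and deduplicates the retained aligned
subsequences into a unique-motif set with provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .align import (
    AlignmentResult,
    EVDParams,
    ScoringScheme,
    align_glocal,
    evalue,
)
from .seq_io import AnnotationTable, ProteinRecord

__all__ = [
    "SearchThresholds",
    "MotifHit",
    "MotifSet",
    "default_min_identity",
    "scan_database",
    "dedup_motifs",
]


def default_min_identity(query_length: int) -> float:
    """Default identity cut-off for a query of the given length.

    A hit must match in at least half the columns, rounded up:
    ``ceil(L/2)/L`` — 57.1% for 7-mers and 55.6% for 9-mers, the
    cut-offs applied to the two packaged query peptides.
    """
    if query_length < 1:
        raise ValueError("query_length must be >= 1")
    return round(100.0 * math.ceil(query_length / 2) / query_length, 1)


@dataclass(frozen=True)
class SearchThresholds:
    """Acceptance cut-offs for a scan: E <= max_evalue, identity >=
    min_identity, at most max_hits reported (best E first)."""

    max_evalue: float = 0.1
    min_identity: float = 57.1
    max_hits: int = 500

    def __post_init__(self):
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if not (0 <= self.min_identity <= 100):
            raise ValueError("min_identity must be within [0, 100]")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")

    @classmethod
    def for_query(cls, query: str, max_evalue: float = 0.1,
                  max_hits: int = 500) -> "SearchThresholds":
        return cls(max_evalue, default_min_identity(len(query)), max_hits)


@dataclass(frozen=True)
class MotifHit:
    """One retained alignment with its protein provenance."""

    accession: str
    gene_symbol: str
    taxon_category: str
    motif_sequence: str
    alignment: AlignmentResult
    query: str

    def __post_init__(self):
        if self.motif_sequence != self.alignment.target_aln.replace("-", ""):
            raise ValueError("motif_sequence must be the ungapped target")


@dataclass(frozen=True)
class MotifSet:
    """Deduplicated motif sequences for one query, with provenance."""

    query: str
    motifs: tuple[str, ...]
    provenance: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.motifs)) != len(self.motifs):
            raise ValueError("motifs must be unique")
        if set(self.provenance) != set(self.motifs):
            raise ValueError("provenance must cover every motif")

    def __len__(self) -> int:
        return len(self.motifs)


def scan_database(
    query: str,
    database: list[ProteinRecord],
    scheme: ScoringScheme,
    evd: EVDParams,
    thresholds: SearchThresholds | None = None,
    annotations: AnnotationTable | None = None,
) -> list[MotifHit]:
    """Scan every record with the query; return passing hits.

    One best glocal alignment per record; hits with
    ``evalue <= max_evalue`` and ``identity >= min_identity`` are kept,
    sorted ascending by E-value (ties by accession) and truncated at
    ``max_hits``. Annotations, when given, fill gene symbol and taxon
    category; otherwise those fields are empty strings.
    """
    if not database:
        raise ValueError("database must be non-empty")
    if thresholds is None:
        thresholds = SearchThresholds.for_query(query)
    hits = []
    for rec in database:
        aln = align_glocal(query, rec.sequence, scheme)
        e = evalue(aln.score, evd)
        if e > thresholds.max_evalue:
            continue
        if aln.identity_percent < thresholds.min_identity:
            continue
        aln = AlignmentResult(
            query_aln=aln.query_aln,
            target_aln=aln.target_aln,
            score=aln.score,
            target_start=aln.target_start,
            target_end=aln.target_end,
            identity_percent=aln.identity_percent,
            evalue=e,
        )
        gene, taxon = "", ""
        if annotations is not None and rec.accession in annotations:
            gene = annotations.gene_symbol(rec.accession)
            taxon = annotations.taxon_category(rec.accession)
        hits.append(
            MotifHit(
                accession=rec.accession,
                gene_symbol=gene,
                taxon_category=taxon,
                motif_sequence=aln.target_aln.replace("-", ""),
                alignment=aln,
                query=query,
            )
        )
    hits.sort(key=lambda h: (h.alignment.evalue, h.accession))
    return hits[: thresholds.max_hits]


def dedup_motifs(hits: list[MotifHit]) -> MotifSet:
    """Collapse hits into unique motif sequences.

    Hits must come from a single query. The best-E occurrence of each
    motif sequence defines its rank; provenance aggregates every
    contributing accession in encounter order. Idempotent: re-running
    on an already-unique set changes nothing.
    """
    queries = {h.query for h in hits}
    if len(queries) > 1:
        raise ValueError(f"hits from mixed queries: {sorted(queries)}")
    query = queries.pop() if queries else ""
    ordered = sorted(
        hits, key=lambda h: (h.alignment.evalue
                             if h.alignment.evalue is not None else 0.0,
                             h.accession),
    )
    motifs: list[str] = []
    prov: dict[str, list[str]] = {}
    for h in ordered:
        if h.motif_sequence not in prov:
            motifs.append(h.motif_sequence)
            prov[h.motif_sequence] = []
        if h.accession not in prov[h.motif_sequence]:
            prov[h.motif_sequence].append(h.accession)
    return MotifSet(
        query=query,
        motifs=tuple(motifs),
        provenance={m: tuple(a) for m, a in prov.items()},
    )
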