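"""GO-term classification, hypergeometric enrichment, taxonomy profile.

Enrichment follows the classic over-representation scheme: for each GO
term carried by at least one study gene, the upper-tail hypergeometric
probability of drawing ``k`` or more annotated genes in a study set of
``n`` from a background of ``N_bg`` containing ``K`` annotated genes,
Benjamini-Hochberg adjusted across tested terms, with fold enrichment
``(k/n) / (K/N_bg)``. Annotations are taken as given (flat — no GO DAG
ancestor propagation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .seq_io import AnnotationTable

logger = logging.getLogger(__name__)

#: Taxonomic vocabulary of the profile (prokaryotes, mammals,
#: vertebrates, invertebrates, plants, other eukaryotes).
TAXON_CATEGORIES = (
    "bacteria", "viruses", "archaea",
    "human", "primates", "other mammals",
    "birds", "fishes", "amphibia",
    "reptiles", "insects", "nematodes",
    "higher plants", "algae",
    "yeast", "fungi", "other eukaryotes",
)

__all__ = [
    "TAXON_CATEGORIES",
    "TaxonProfile",
    "EnrichmentResult",
    "classify_terms",
    "enrich",
    "bh_fdr",
    "taxon_profile",
]


@dataclass(frozen=True)
class TaxonProfile:
    """Unique-gene counts and percentages per taxonomic category."""

    counts: dict
    percentages: dict

    def __post_init__(self):
        total = sum(self.counts.values())
        if total and abs(sum(self.percentages.values()) - 100.0) > 1e-9:
            raise ValueError("percentages must sum to 100")


@dataclass(frozen=True)
class EnrichmentResult:
    """Counts and statistics for one GO term."""

    term: str
    namespace: str
    k: int        # study genes carrying the term
    n: int        # study set size
    K: int        # background genes carrying the term
    N_bg: int     # background size
    p_value: float
    fdr: float
    fold_enrichment: float
    significant: bool

    def __post_init__(self):
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError("require 0 <= k <= min(n, K)")
        if not (0 <= self.p_value <= 1):
            raise ValueError("p_value must lie in [0, 1]")
        if self.fdr < self.p_value - 1e-12:
            raise ValueError("fdr cannot be below the nominal p-value")


def _gene_terms(genes, annotations: AnnotationTable, label: str):
    """Map gene -> union of GO terms over its accessions; genes absent
    from the annotation table are logged and skipped."""
    by_gene: dict[str, set] = {}
    missing = []
    for g in genes:
        if g in annotations:
            acc_terms = annotations.go_terms(g)
        else:
            acc_terms = None
            for acc, row in annotations.rows.items():
                if row["gene_symbol"] == g:
                    acc_terms = (acc_terms or frozenset()) | row["go_terms"]
            if acc_terms is None:
                missing.append(g)
                continue
        by_gene.setdefault(g, set()).update(acc_terms)
    if missing:
        logger.warning(
            "%d %s gene(s) absent from annotations, skipped: %s%s",
            len(missing), label, missing[:5], "..." if len(missing) > 5 else "",
        )
    return by_gene


def classify_terms(study_genes, annotations: AnnotationTable) -> list:
    """Count distinct study genes per GO term.

    A gene contributes at most once per term but may contribute to many
    terms. Returns ``((term, namespace), count)`` pairs ranked by
    descending count, ties alphabetical. Empty study set is an error.
    """
    genes = list(dict.fromkeys(study_genes))
    if not genes:
        raise ValueError("study gene set is empty")
    by_gene = _gene_terms(genes, annotations, "study")
    counts: dict[tuple, int] = {}
    for terms in by_gene.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    study_genes,
    background_genes,
    annotations: AnnotationTable,
    fdr_cutoff: float = 0.2,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of GO terms in the study set.

    Only terms with ``k >= 1`` study genes are tested (untestable terms
    would merely inflate the correction). Results are sorted by
    descending fold enrichment, then ascending p, then term id; those
    with ``fdr <= fdr_cutoff`` are flagged significant.
    """
    study = list(dict.fromkeys(study_genes))
    background = list(dict.fromkeys(background_genes))
    if not study or not background:
        raise ValueError("study and background sets must be non-empty")
    extra = set(study) - set(background)
    if extra:
        raise ValueError(
            f"study genes missing from background: {sorted(extra)[:5]}"
        )
    study_terms = _gene_terms(study, annotations, "study")
    bg_terms = _gene_terms(background, annotations, "background")
    n = len(study_terms)
    N_bg = len(bg_terms)
    k_counts: dict[tuple, int] = {}
    for terms in study_terms.values():
        for t in terms:
            k_counts[t] = k_counts.get(t, 0) + 1
    K_counts: dict[tuple, int] = {}
    for terms in bg_terms.values():
        for t in terms:
            K_counts[t] = K_counts.get(t, 0) + 1

    tested = sorted(k_counts)
    pvals = []
    for t in tested:
        k, K = k_counts[t], K_counts[t]
        # upper tail: P[X >= k], X ~ Hypergeom(N_bg, K, n)
        pvals.append(float(hypergeom.sf(k - 1, N_bg, K, n)))
    fdrs = bh_fdr(pvals)

    results = []
    for (term, ns), p, q in zip(tested, pvals, fdrs):
        k, K = k_counts[(term, ns)], K_counts[(term, ns)]
        fold = (k / n) / (K / N_bg)
        results.append(
            EnrichmentResult(
                term=term, namespace=ns, k=k, n=n, K=K, N_bg=N_bg,
                p_value=p, fdr=float(min(q, 1.0)), fold_enrichment=fold,
                significant=bool(q <= fdr_cutoff),
            )
        )
    results.sort(key=lambda r: (-r.fold_enrichment, r.p_value, r.term))
    return results


def taxon_profile(hits, annotations: AnnotationTable) -> TaxonProfile:
    """Distribution of unique genes over taxonomic categories.

    ``hits`` may be MotifHit objects or accession strings. A gene
    symbol observed in several categories (orthologs across species) is
    counted once in each — every such occurrence is treated as its own
    unique gene. The full category vocabulary is always present, zeros
    included; an annotation outside the vocabulary is an error.
    """
    pairs = set()
    for h in hits:
        acc = h if isinstance(h, str) else h.accession
        if acc not in annotations:
            logger.warning("accession %s not annotated, skipped", acc)
            continue
        cat = annotations.taxon_category(acc)
        if cat not in TAXON_CATEGORIES:
            raise ValueError(f"unknown taxon category {cat!r} for {acc}")
        pairs.add((annotations.gene_symbol(acc), cat))
    counts = {c: 0 for c in TAXON_CATEGORIES}
    for _, cat in pairs:
        counts[cat] += 1
    total = sum(counts.values())
    percentages = {
        c: (100.0 * v / total if total else 0.0) for c, v in counts.items()
    }
    return TaxonProfile(counts=counts, percentages=percentages)
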