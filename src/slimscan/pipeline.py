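"""End-to-end orchestration: search -> dedup -> conservation ->
taxonomy -> enrichment, with a reproducibility manifest.

A run is fully described by a PipelineConfig; two runs with the same
config and seed produce byte-identical artifacts (the manifest records
inputs, parameters and versions but no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

from . import __version__
from .align import build_scoring, calibrate_evd
from .conservation import consensus_notation, logo_columns, position_frequencies
from .annotation_stats import enrich, taxon_profile
from .motif_search import SearchThresholds, dedup_motifs, scan_database
from .seq_io import read_annotations, read_fasta, write_table

logger = logging.getLogger(__name__)

ARTIFACTS = (
    "hits.tsv", "motifs.txt", "pfm.tsv", "consensus.txt",
    "logo.tsv", "taxonomy.tsv", "enrich.tsv", "manifest.json",
)

__all__ = ["PipelineConfig", "run_pipeline", "ARTIFACTS"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything that affects a pipeline run."""

    query: str
    database: str
    annotations: str
    output_dir: str
    matrix: str = "BLOSUM50"
    gap_open: int = -10
    gap_extend: int = -2
    max_evalue: float = 0.1
    min_identity: float | None = None  # None: derived from query length
    max_hits: int = 500
    calibration_samples: int = 500
    alt_threshold: float = 5.0
    fdr_cutoff: float = 0.2
    logo_corrected: bool = True
    seed: int = 17

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def thresholds(self) -> SearchThresholds:
        if self.min_identity is None:
            return SearchThresholds.for_query(
                self.query, self.max_evalue, self.max_hits
            )
        return SearchThresholds(self.max_evalue, self.min_identity, self.max_hits)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in fixed order; return the artifact manifest.

    Writes hits.tsv, motifs.txt, pfm.tsv, consensus.txt, logo.tsv,
    taxonomy.tsv, enrich.tsv and manifest.json into the output
    directory. Stage errors abort with the stage name and cause.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds()

    database = _stage("read_inputs")(read_fasta)(config.database)
    annotations = read_annotations(config.annotations)

    scheme = build_scoring(config.matrix, config.gap_open, config.gap_extend)
    lengths = [len(r) for r in database]
    mean = sum(lengths) / len(lengths)
    sd = (sum((x - mean) ** 2 for x in lengths) / max(len(lengths) - 1, 1)) ** 0.5
    evd = _stage("calibrate")(calibrate_evd)(
        scheme, config.query, (mean, max(sd, 1.0)),
        n_samples=config.calibration_samples, seed=config.seed,
    )

    hits = _stage("scan")(scan_database)(
        config.query, database, scheme, evd, thresholds, annotations
    )
    write_table(
        (
            {
                "accession": h.accession,
                "gene_symbol": h.gene_symbol,
                "taxon_category": h.taxon_category,
                "motif": h.motif_sequence,
                "query_aln": h.alignment.query_aln,
                "target_aln": h.alignment.target_aln,
                "target_start": h.alignment.target_start,
                "target_end": h.alignment.target_end,
                "score": h.alignment.score,
                "identity_percent": h.alignment.identity_percent,
                "evalue": h.alignment.evalue,
            }
            for h in hits
        ),
        outdir / "hits.tsv",
        ["accession", "gene_symbol", "taxon_category", "motif", "query_aln",
         "target_aln", "target_start", "target_end", "score",
         "identity_percent", "evalue"],
    )

    motif_set = _stage("dedup")(dedup_motifs)(hits)
    (outdir / "motifs.txt").write_text(
        "".join(f"{m}\n" for m in motif_set.motifs)
    )

    # The PFM needs equal-length gap-free motifs; hits whose alignment
    # used gaps yield off-length motif sequences and are set aside.
    counted = [m for m in motif_set.motifs if len(m) == len(config.query)]
    if len(counted) < len(motif_set):
        logger.warning(
            "%d gapped motif(s) excluded from conservation analysis",
            len(motif_set) - len(counted),
        )
    if counted:
        pfm = _stage("conservation")(position_frequencies)(counted)
        pfm.to_frame().to_csv(
            outdir / "pfm.tsv", sep="\t", index=False, float_format="%.6g"
        )
        consensus = consensus_notation(pfm, config.alt_threshold)
        (outdir / "consensus.txt").write_text(consensus.notation + "\n")
        columns = logo_columns(pfm, corrected=config.logo_corrected)
        write_table(
            (
                {
                    "position": i + 1,
                    "information_content": c.information_content,
                    **{aa: c.symbol_heights.get(aa, 0.0)
                       for aa in sorted(set().union(*(cc.symbol_heights
                                                      for cc in columns)))},
                }
                for i, c in enumerate(columns)
            ),
            outdir / "logo.tsv",
            ["position", "information_content"]
            + sorted(set().union(*(c.symbol_heights for c in columns))),
        )
    else:
        for name in ("pfm.tsv", "consensus.txt", "logo.tsv"):
            (outdir / name).write_text("")

    profile = _stage("taxonomy")(taxon_profile)(hits, annotations)
    write_table(
        (
            {"taxon_category": c, "unique_genes": profile.counts[c],
             "percent": profile.percentages[c]}
            for c in profile.counts
        ),
        outdir / "taxonomy.tsv",
        ["taxon_category", "unique_genes", "percent"],
    )

    study_genes = sorted({h.gene_symbol for h in hits if h.gene_symbol})
    background = sorted({r["gene_symbol"] for r in annotations.rows.values()})
    if study_genes:
        results = _stage("enrichment")(enrich)(
            study_genes, background, annotations, config.fdr_cutoff
        )
    else:
        results = []
    write_table(
        (
            {
                "term": r.term, "namespace": r.namespace, "k": r.k, "n": r.n,
                "K": r.K, "N_bg": r.N_bg, "fold_enrichment": r.fold_enrichment,
                "p_value": r.p_value, "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in results
        ),
        outdir / "enrich.tsv",
        ["term", "namespace", "k", "n", "K", "N_bg", "fold_enrichment",
         "p_value", "fdr", "significant"],
    )

    manifest = {
        "version": __version__,
        "inputs": {
            "database": {"path": str(config.database),
                         "sha256": _sha256(config.database)},
            "annotations": {"path": str(config.annotations),
                            "sha256": _sha256(config.annotations)},
        },
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("database", "annotations", "output_dir")
        },
        "evd": {"mu": evd.mu, "beta": evd.beta,
                "database_size": evd.database_size},
        "thresholds": asdict(thresholds),
        "counts": {
            "database_records": len(database),
            "hits": len(hits),
            "unique_motifs": len(motif_set),
            "enriched_terms": sum(r.significant for r in results),
        },
        "artifacts": list(ARTIFACTS),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
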