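"""Synthetic protein databases with planted profile-drawn motifs.

Stands in for a real protein knowledgebase in tests and benchmarks:
background sequences of realistic length, a configurable fraction of
proteins carrying one motif drawn from a per-position categorical
profile, taxonomy labels drawn from a fixed category mixture, and GO
annotations in which chosen terms are over-represented among planted
proteins by a configured fold. The generator emits an exact truth
table, so scan results can be scored for precision and recall.

The two packaged profiles encode the observed per-position residue
frequencies of the motif families around the query peptides LDSYQCT
(alpha-fetoprotein residues 14-20) and EMTPVNPGV (GIP-9): e.g. an
invariant cysteine at position 6 of the 7-mer family (100%), aspartate
at 82.9% at position 2, and near-invariant prolines (96%/98%) at
positions 4 and 7 of the 9-mer family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AMINO_ACIDS
from .seq_io import AnnotationTable, ProteinRecord
from .annotation_stats import TAXON_CATEGORIES

__all__ = [
    "MotifProfile",
    "GOTermSpec",
    "SyntheticConfig",
    "PlantedTruth",
    "AFP14_20_QUERY",
    "GIP9_QUERY",
    "AFP14_20_PROFILE",
    "GIP9_PROFILE",
    "SWISSPROT_COMPOSITION",
    "draw_motifs",
    "generate_database",
]

AFP14_20_QUERY = "LDSYQCT"
GIP9_QUERY = "EMTPVNPGV"


@dataclass(frozen=True)
class MotifProfile:
    """Per-position categorical residue distributions for one motif."""

    name: str
    probs: np.ndarray  # L x 20, rows sum to 1, columns follow AMINO_ACIDS

    def __post_init__(self):
        if self.probs.ndim != 2 or self.probs.shape[1] != 20:
            raise ValueError("probs must be an L x 20 matrix")
        if (self.probs < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position must sum to 1")

    @property
    def length(self) -> int:
        return self.probs.shape[0]


def _profile(name: str, rows: list[dict]) -> MotifProfile:
    probs = np.zeros((len(rows), 20))
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for p, row in enumerate(rows):
        for aa, frac in row.items():
            probs[p, idx[aa]] = frac
        probs[p] /= probs[p].sum()
    return MotifProfile(name=name, probs=probs)


#: 7-mer family profile: headline frequencies per position with the
#: remaining mass spread over physicochemically plausible minor
#: residues, each kept below the 5% consensus threshold.
AFP14_20_PROFILE = _profile("AFP14-20", [
    {"L": 0.573, "M": 0.20, "I": 0.12, "V": 0.08, "A": 0.027},
    {"D": 0.829, "N": 0.10, "E": 0.06, "A": 0.011},
    {"S": 0.548, "T": 0.20, "K": 0.15, "E": 0.08, "A": 0.022},
    {"Y": 0.606, "F": 0.233, "W": 0.045, "H": 0.045, "L": 0.035, "A": 0.036},
    {"Q": 0.678, "K": 0.12, "D": 0.10, "R": 0.06, "A": 0.042},
    {"C": 1.0},
    {"T": 0.453, "S": 0.20, "A": 0.043375, "G": 0.043375, "N": 0.043375,
     "D": 0.043375, "E": 0.043375, "K": 0.043375, "R": 0.043375,
     "V": 0.043375},
])

#: 9-mer family profile, same construction.
GIP9_PROFILE = _profile("GIP-9", [
    {"E": 0.604, "D": 0.15, "Q": 0.10, "K": 0.048, "G": 0.049, "A": 0.049},
    {"M": 0.354, "L": 0.25, "I": 0.20, "V": 0.15, "A": 0.046},
    {"T": 0.518, "S": 0.129, "A": 0.044125, "G": 0.044125, "N": 0.044125,
     "D": 0.044125, "E": 0.044125, "K": 0.044125, "R": 0.044125,
     "V": 0.044125},
    {"P": 0.96, "A": 0.02, "S": 0.02},
    {"V": 0.55, "I": 0.204, "L": 0.079, "A": 0.042, "G": 0.042, "T": 0.042,
     "M": 0.041},
    {"N": 0.568, "D": 0.15, "S": 0.10, "A": 0.046, "G": 0.046, "T": 0.045,
     "E": 0.045},
    {"P": 0.98, "A": 0.01, "S": 0.01},
    {"G": 0.92, "A": 0.04, "S": 0.04},
    {"V": 0.471, "I": 0.182, "L": 0.121, "A": 0.046, "G": 0.045, "T": 0.045,
     "M": 0.045, "F": 0.045},
])

DEFAULT_PROFILES = {
    AFP14_20_QUERY: AFP14_20_PROFILE,
    GIP9_QUERY: GIP9_PROFILE,
}

#: Approximate Swiss-Prot residue composition (optional alternative to
#: the uniform default background).
SWISSPROT_COMPOSITION = np.array([
    0.0826, 0.0138, 0.0546, 0.0672, 0.0386,  # A C D E F
    0.0708, 0.0227, 0.0591, 0.0580, 0.0965,  # G H I K L
    0.0241, 0.0406, 0.0473, 0.0393, 0.0553,  # M N P Q R
    0.0665, 0.0535, 0.0110, 0.0292, 0.0687,  # S T W Y V
])
SWISSPROT_COMPOSITION /= SWISSPROT_COMPOSITION.sum()


@dataclass(frozen=True)
class GOTermSpec:
    """One catalog term: background annotation probability and the fold
    by which planted proteins are over-annotated."""

    term: str
    namespace: str
    background_prob: float
    planted_fold: float = 1.0

    def __post_init__(self):
        if not (0 < self.background_prob <= 1):
            raise ValueError("background_prob must lie in (0, 1]")
        if self.planted_fold < 0:
            raise ValueError("planted_fold must be non-negative")


def default_go_catalog() -> tuple[GOTermSpec, ...]:
    """A small flat catalog; two stress-response terms are planted."""
    return (
        GOTermSpec("GO:0016491", "MF", 0.05, 4.0),   # oxidoreductase activity
        GOTermSpec("GO:0006979", "BP", 0.05, 3.0),   # response to oxidative stress
        GOTermSpec("GO:0046872", "MF", 0.25, 1.0),   # metal ion binding
        GOTermSpec("GO:0003677", "MF", 0.15, 1.0),   # DNA binding
        GOTermSpec("GO:0005524", "MF", 0.15, 1.0),   # ATP binding
        GOTermSpec("GO:0009055", "MF", 0.06, 1.0),   # electron transfer activity
        GOTermSpec("GO:0016740", "MF", 0.12, 1.0),   # transferase activity
        GOTermSpec("GO:0006355", "BP", 0.12, 1.0),   # regulation of transcription
        GOTermSpec("GO:0006412", "BP", 0.10, 1.0),   # translation
        GOTermSpec("GO:0006281", "BP", 0.06, 1.0),   # DNA repair
        GOTermSpec("GO:0008152", "BP", 0.30, 1.0),   # metabolic process
        GOTermSpec("GO:0006952", "BP", 0.08, 1.0),   # defense response
    )


def default_taxon_mixture() -> dict:
    """Bacteria-dominated mixture over the fixed category vocabulary."""
    mix = {
        "bacteria": 0.55, "viruses": 0.04, "archaea": 0.04,
        "human": 0.05, "primates": 0.02, "other mammals": 0.05,
        "birds": 0.03, "fishes": 0.04, "amphibia": 0.01,
        "reptiles": 0.01, "insects": 0.03, "nematodes": 0.02,
        "higher plants": 0.05, "algae": 0.01,
        "yeast": 0.01, "fungi": 0.02, "other eukaryotes": 0.02,
    }
    assert abs(sum(mix.values()) - 1.0) < 1e-12
    return mix


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults give a 200-protein database with
    half the proteins carrying one planted 7-mer-family motif."""

    n_proteins: int = 200
    length_mean: float = 300.0
    length_sd: float = 100.0
    min_length: int = 50
    background_composition: np.ndarray | None = None  # uniform when None
    planting_rate: float = 0.5
    profile: MotifProfile = AFP14_20_PROFILE
    #: resample profile draws until they differ from the reference motif
    #: in at most this many positions (None disables the constraint)
    max_mismatches: int | None = 2
    reference_motif: str | None = None  # defaults to the profile's argmax
    taxon_mixture: dict = field(default_factory=default_taxon_mixture)
    go_catalog: tuple[GOTermSpec, ...] = field(default_factory=default_go_catalog)
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.planting_rate <= 1):
            raise ValueError("planting_rate must lie in [0, 1]")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        total = sum(self.taxon_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("taxon mixture must sum to 1")
        unknown = set(self.taxon_mixture) - set(TAXON_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown taxon categories: {sorted(unknown)}")


@dataclass(frozen=True)
class PlantedTruth:
    """Exact record of what the generator planted."""

    proteins: pd.DataFrame  # accession, planted, motif, position (1-based)
    term_folds: dict        # (term, namespace) -> configured fold

    def to_table(self) -> pd.DataFrame:
        return self.proteins.copy()


def consensus_of(profile: MotifProfile) -> str:
    """Most probable residue at each position (ties alphabetical)."""
    out = []
    for p in range(profile.length):
        row = profile.probs[p]
        top = row.max()
        out.append(min(AMINO_ACIDS[i] for i in np.flatnonzero(row == top)))
    return "".join(out)


def draw_motifs(
    profile: MotifProfile,
    n: int,
    seed: int | np.random.Generator = 0,
    max_mismatches: int | None = None,
    reference: str | None = None,
) -> list[str]:
    """Draw ``n`` motifs i.i.d. from the profile, positions independent.

    With ``max_mismatches`` set, draws are rejection-sampled until they
    differ from ``reference`` (default: the profile's per-position
    argmax) in at most that many positions — emulating families whose
    members stay within a fixed identity of the prototype.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if max_mismatches is not None and reference is None:
        reference = consensus_of(profile)
    cum = np.cumsum(profile.probs, axis=1)
    out = []
    while len(out) < n:
        u = rng.random(profile.length)
        draws = (cum < u[:, None]).sum(axis=1)
        motif = "".join(AMINO_ACIDS[k] for k in draws)
        if max_mismatches is not None:
            mm = sum(a != b for a, b in zip(motif, reference))
            if mm > max_mismatches:
                continue
        out.append(motif)
    return out


def generate_database(
    config: SyntheticConfig,
) -> tuple[list[ProteinRecord], AnnotationTable, PlantedTruth]:
    """Generate (records, annotations, truth) deterministically per seed.

    Each protein gets a background sequence; planted proteins (Bernoulli
    ``planting_rate``) have one profile-drawn motif substituted at a
    uniform-random position. Taxon labels follow the configured mixture;
    each GO term is assigned with its background probability, multiplied
    by its planted fold (capped at 1) for planted proteins.
    """
    rng = np.random.default_rng(config.seed)
    comp = (np.full(20, 0.05) if config.background_composition is None
            else np.asarray(config.background_composition, dtype=float))
    comp = comp / comp.sum()
    taxa = list(config.taxon_mixture)
    taxon_p = np.array([config.taxon_mixture[t] for t in taxa])

    records, truth_rows = [], []
    table = AnnotationTable()
    width = len(str(config.n_proteins))
    for i in range(config.n_proteins):
        length = max(config.min_length,
                     int(round(rng.normal(config.length_mean, config.length_sd))))
        seq = "".join(AMINO_ACIDS[k] for k in rng.choice(20, size=length, p=comp))
        planted = bool(rng.random() < config.planting_rate)
        motif, position = "", 0
        if planted:
            if config.profile.length > length:
                raise ValueError("motif longer than protein sequence")
            motif = draw_motifs(
                config.profile, 1, rng,
                max_mismatches=config.max_mismatches,
                reference=config.reference_motif,
            )[0]
            position = int(rng.integers(0, length - config.profile.length + 1)) + 1
            seq = (seq[: position - 1] + motif
                   + seq[position - 1 + config.profile.length:])
        accession = f"SYN{i + 1:0{width}d}"
        gene = f"gene{i + 1:0{width}d}"
        taxon = taxa[int(rng.choice(len(taxa), p=taxon_p))]
        terms = []
        for spec in config.go_catalog:
            prob = spec.background_prob
            if planted:
                prob = min(1.0, prob * spec.planted_fold)
            if rng.random() < prob:
                terms.append((spec.term, spec.namespace))
        records.append(ProteinRecord(accession, seq, "synthetic protein"))
        table.add(accession, gene, taxon, terms)
        truth_rows.append(
            {"accession": accession, "gene_symbol": gene, "planted": planted,
             "motif": motif, "position": position}
        )

    truth = PlantedTruth(
        proteins=pd.DataFrame(truth_rows),
        term_folds={(s.term, s.namespace): s.planted_fold
                    for s in config.go_catalog},
    )
    return records, table, truth
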