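# Methods

## Problem and scope

`slimscan` searches a protein database for short linear motifs (SLiMs)
similar to a short query peptide, then characterises the retrieved motif
family: per-position residue frequencies and a consensus notation,
sequence-logo information content, the taxonomic spread of the carrying
genes, and GO-term over-representation. The two packaged queries are the
alpha-fetoprotein-derived peptides LDSYQCT (AFP residues 14–20) and
EMTPVNPGV (GIP-9). Real protein knowledgebases are supported through
plain FASTA plus an annotation TSV; a synthetic generator with planted
motifs provides ground truth for benchmarking.

## Glocal alignment

The scan unit is a *glocal* alignment: global over the query (every
query residue is aligned, possibly to a gap) and local over the target
(leading and trailing target residues are free). This matches the
semantics of GLSEARCH-style peptide searches, where the biological
question is "does the whole peptide occur somewhere in this protein".

Scoring is BLOSUM50 (Biopython's packaged NCBI matrix, restricted to
the 20 canonical residues plus X) with affine gap runs costing
`gap_open + (len − 1)·gap_extend`; defaults are gap open −10 and gap
extend −2. The dynamic program is the standard three-state Gotoh
recursion (substitution / query-residue-over-gap /
target-residue-over-gap) with the start state free at every target
offset and the optimum taken over all end offsets of the last query
row. Ties in the traceback prefer substitution, then gap-in-target,
then gap-in-query, and smaller target end coordinates, so a run always
returns one deterministic optimum. Correctness is checked against an
exhaustive enumeration of every gapped alignment on small instances.

**Identity degree** is the percentage of alignment columns in which
query and target residues are identical, with gap columns counted in
the denominator, rounded to one decimal. For gap-free alignments of a
7-mer this gives the familiar k/7 values (4/7 = 57.1, 6/7 = 85.7); for
gapped alignments gaps dilute identity. This denominator convention is
a package decision: published hit tables rarely print gap characters,
and only the column-count convention reproduces the printed gap-free
values while still defining a value for gapped optima.

## E-value model

Significance uses an empirical extreme-value model: the best glocal
score of a fixed short query against a random protein is approximately
Gumbel distributed. `calibrate_evd` aligns the query against
`n_samples` random sequences (uniform residue composition by default; a
Swiss-Prot-like composition table is packaged) whose lengths follow the
database's length distribution, then matches sample mean and variance
to the Gumbel moments (`beta = sqrt(6·var)/π`,
`mu = mean − γ·beta`). `evalue` converts a score to
`E = database_size · (1 − exp(−exp(−(s − mu)/beta)))`.

`database_size` defaults to 1, so the reported E-value is the
*per-sequence* upper-tail probability of the score. This is a
deliberate operating-point choice: a moment-fit Gumbel describes the
bulk of the chance-score distribution well but substantially
overestimates the extreme upper tail of glocal scores for short bounded
queries (a 7-mer's score cannot exceed its self-score, while the fitted
Gumbel assigns that region appreciable mass). Scaling such inflated
tail estimates by the full database size would push genuinely
motif-like scores past any fixed cut-off on desk-scale databases, even
though the same family of hits passes the corresponding cut-off in
production search tools, whose length- and score-calibrated statistics
are far sharper in the tail. Per-sequence scaling keeps the default
cut-off (E ≤ 0.1) at the operating point where near-prototype motifs
pass and random sequences fail at a calibrated ~10% per-sequence rate;
`with_database_size` rescales to whole-database expected counts when
those are wanted, and E-values double exactly when `database_size`
doubles. Reported E-values are *not* comparable with any specific
production tool's numbers.

## Search thresholds and deduplication

A hit must satisfy both `evalue ≤ max_evalue` (default 0.1) and
`identity ≥ min_identity`. The default identity cut-off requires a
match in at least half the columns, rounded up: `ceil(L/2)/L`, i.e.
57.1% for 7-mers and 55.6% for 9-mers — the cut-offs used with the two
packaged queries. One best alignment is kept per database record; hits
are sorted by ascending E-value and truncated at `max_hits`
(default 500).

Deduplication is at the motif-sequence level: the retained aligned
subsequences are collapsed to unique strings, the best-E occurrence
fixing the rank, with every contributing accession kept as provenance.
Gapped optima can yield motif sequences whose length differs from the
query; the pipeline sets these aside (with a warning) before
conservation analysis, which requires equal-length gap-free motifs.

## Conservation statistics

For `b` equal-length motifs the position frequency matrix holds
`N = a/b × 100` per position and residue, where `a` counts the residue
at that position. The consensus notation concatenates, per position,
the majority residue and a bracketed list of alternates whose frequency
is at least `alt_threshold` percent (default 5%, inclusive), ordered by
descending frequency with alphabetical tie-breaks; majority ties are
broken alphabetically and logged. Motifs containing X are excluded from
counting with a warning.

Logo columns report information content
`IC = log2 20 − H − e_n` in bits, with `H` the Shannon entropy of the
position's frequencies and `e_n = 19/(2·ln2·b)` the small-sample
correction; residue stack height is frequency × IC. The correction is
off in the PFM/consensus path (the frequency definition above has
none) and on by default for logo output, matching common logo-rendering
practice; both are exposed as a flag.

## Taxonomy and GO enrichment

The taxonomy profile counts unique genes per category over a fixed
17-category vocabulary (bacteria, viruses, archaea, human, primates,
other mammals, birds, fishes, amphibia, reptiles, insects, nematodes,
higher plants, algae, yeast, fungi, other eukaryotes). A gene symbol
observed in several categories (orthologs across species) counts once
in each category.

Enrichment is the classical over-representation test on flat
annotations (no GO-DAG ancestor propagation): for each term annotated
to at least one study gene, `p = P[X ≥ k]` with
`X ~ Hypergeometric(N_bg, K, n)` (SciPy's survival function), where `n`
is the study size, `N_bg` the background size (all genes of the
annotation table), and `k`/`K` the study/background genes carrying the
term. Benjamini–Hochberg adjustment runs across the tested terms only —
terms with `k = 0` cannot be enriched and would merely inflate the
correction. Fold enrichment is `(k/n)/(K/N_bg)`; results are sorted by
descending fold, then ascending p, and flagged at `fdr ≤ 0.2` by
default. Unannotated study genes are logged and skipped.

## Synthetic data generator

The generator emulates the structure the pipeline consumes, not any
real knowledgebase. Defaults: 200 proteins, lengths normal(300, 100)
floored at 50, uniform background composition (a Swiss-Prot-like
composition is packaged as an option), planting rate 0.5, taxon labels
from a bacteria-dominated mixture over the 17 categories, and a small
flat GO catalog in which two stress-response terms are planted at folds
4 and 3 among motif-carrying proteins.

Planted motifs are drawn i.i.d. per position from a packaged profile.
The 7-mer profile encodes the observed family frequencies around
LDSYQCT — an invariant cysteine at position 6 (100%), aspartate 82.9%
at position 2, leucine 57.3% at position 1, and so on — with the
unassigned probability mass spread over plausible minor residues, each
kept below the 5% consensus threshold; the 9-mer profile does the same
for EMTPVNPGV (prolines at 96%/98%, glycine 92%). By default draws are
rejection-sampled to at most two mismatches from the profile consensus
(≥ 71.4% identity for a 7-mer), emulating a motif family whose members
stay within a fixed identity of the prototype; set
`max_mismatches=None` for unconstrained draws. One motif is substituted
(length-preserving) at a uniform-random position of each planted
protein, and an exact truth table (planted flag, motif, 1-based
position, per-term fold) is emitted.

What the generator does **not** emulate: positional covariance within
motifs (draws are position-independent, as is the position-marginal
analysis downstream), realistic taxonomy abundances, GO DAG structure,
protein domain composition, or low-complexity/disordered regions.
Passing benchmarks on synthetic data therefore demonstrates the
machinery (alignment, calibration, counting, testing), not performance
on real UniProtKB-scale data.

## Numerical choices and degenerate inputs

- Gumbel fit refuses score samples with zero variance and fewer than
  100 calibration samples; E-values are clipped to
  `[0, database_size]`, and the double-exponential switches to its
  asymptotic form for large scores to avoid underflow to exactly 0.
- FASTA residues B, Z, U, O map to X (scored with the BLOSUM50 X row);
  any other non-alphabet character is a parse error naming the line.
- PFM rows must sum to 100 within 1e−9; logo IC is floored at 0 after
  the small-sample correction.
- The aligner raises on empty query or target; an all-gap-query
  optimum (possible only under pathological scoring) yields an empty
  target span.
- Pipeline reruns are byte-identical for identical config and seed: the
  manifest records input hashes, parameters and versions but no
  timestamps, and every stochastic step derives from the single
  configured seed.

## Problem sizes

Benchmarks and tests run at desk scale by design: databases of 40–200
proteins of mean length 150–300, 150–500 calibration samples, motif
sets of ~200, enrichment backgrounds of up to 1000 genes, and oracle
sweeps limited to instances small enough for exhaustive enumeration
(queries ≤ 4, targets ≤ 7; populations ≤ 25). Database-scale published
counts (hundreds of retrieved proteins per section of a full
knowledgebase) depend on knowledgebase snapshots and are out of scope.

## Known limitations

- E-values are an empirical per-sequence significance, not calibrated
  against any production search tool; only their ordering and rough
  magnitude are meaningful.
- Identity thresholds for query lengths other than 7 and 9 follow the
  `ceil(L/2)/L` generalisation, which is a convention, not a fitted
  rule.
- Enrichment treats annotations as flat; with DAG propagation the
  background counts `K` would grow for ancestral terms and p-values
  would change.
- The consensus notation depends only on the 5% threshold rule; no
  residue-group pooling (e.g. aromatic or hydroxyl classes) is applied.
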