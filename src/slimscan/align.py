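"""Glocal (global-in-query, local-in-target) affine-gap alignment.

This is the computational core of the motif scan: every alignment must
consume the entire query peptide, but may start and end anywhere on the
target protein (free end gaps on the target only) — the semantics of
FASTA's GLSEARCH. Scoring is an exchangeable substitution matrix
(BLOSUM50 by default) with affine gap runs costing
``gap_open + (len - 1) * gap_extend``.

Statistical significance is an empirical extreme-value model: the best
glocal score of a short query against a random protein is approximately
Gumbel distributed, so we calibrate location/scale by the method of
moments on scores against shuffled-composition sequences and convert
scores to database-level E-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Align import substitution_matrices

#: The 20 canonical residues, alphabetical; X is the ambiguity catch-all.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"

_EULER_GAMMA = 0.5772156649015329

__all__ = [
    "AMINO_ACIDS",
    "ALPHABET",
    "ScoringScheme",
    "AlignmentResult",
    "EVDParams",
    "build_scoring",
    "align_glocal",
    "identity_degree",
    "calibrate_evd",
    "evalue",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``gap_open`` is charged for the first residue of a gap run and
    ``gap_extend`` for each additional residue; both are non-positive,
    with ``gap_open <= gap_extend``.
    """

    name: str
    matrix: np.ndarray  # 21x21 int array over ALPHABET
    gap_open: int = -10
    gap_extend: int = -2
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError(
                f"require gap_open <= gap_extend <= 0, got "
                f"({self.gap_open}, {self.gap_extend})"
            )
        if self.matrix.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError("matrix must be 21x21 over the residue alphabet")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")
        object.__setattr__(
            self, "_index", {aa: i for i, aa in enumerate(ALPHABET)}
        )

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[self._index[a], self._index[b]])


@dataclass(frozen=True)
class AlignmentResult:
    """One optimal glocal alignment of a full query to a target region.

    Coordinates are 1-based inclusive on the (ungapped) target.
    """

    query_aln: str
    target_aln: str
    score: int
    target_start: int
    target_end: int
    identity_percent: float
    evalue: float | None = None

    def __post_init__(self):
        if len(self.query_aln) != len(self.target_aln):
            raise ValueError("aligned strings must have equal length")
        span = len(self.target_aln) - self.target_aln.count("-")
        if self.target_end - self.target_start + 1 != span:
            raise ValueError("target coordinates inconsistent with alignment")


@dataclass(frozen=True)
class EVDParams:
    """Gumbel (type-I extreme value) parameters for chance glocal scores.

    ``mu``/``beta`` describe the per-sequence best-score distribution;
    ``database_size`` is the number of sequences the E-value is scaled to.
    """

    mu: float
    beta: float
    database_size: int = 1

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("Gumbel scale beta must be positive")
        if self.database_size < 1:
            raise ValueError("database_size must be >= 1")


def build_scoring(
    matrix_name: str = "BLOSUM50",
    gap_open: int = -10,
    gap_extend: int = -2,
) -> ScoringScheme:
    """Load a named substitution matrix and validate the gap penalties.

    Only BLOSUM-family names shipped with Biopython are recognised;
    the default is the BLOSUM50 / −10 / −2 scheme used for short-peptide
    database scans.
    """
    try:
        full = substitution_matrices.load(matrix_name)
    except FileNotFoundError:
        raise ValueError(f"unknown substitution matrix: {matrix_name!r}")
    mat = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=int)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            mat[i, j] = int(full[a, b])
    return ScoringScheme(matrix_name, mat, int(gap_open), int(gap_extend))


def identity_degree(alignment: AlignmentResult | tuple[str, str]) -> float:
    """Percent identity over all alignment columns, one decimal.

    Gap columns count in the denominator but can never match, so gaps
    dilute identity. Gap-free identical strings give exactly 100.0.
    """
    if isinstance(alignment, AlignmentResult):
        qa, ta = alignment.query_aln, alignment.target_aln
    else:
        qa, ta = alignment
    if len(qa) != len(ta) or not qa:
        raise ValueError("aligned strings must be non-empty and equal length")
    matches = sum(1 for a, b in zip(qa, ta) if a == b and a != "-")
    return round(100.0 * matches / len(qa), 1)


_NEG_INF = float("-inf")


def align_glocal(
    query: str,
    target: str,
    scheme: ScoringScheme,
    evd: EVDParams | None = None,
) -> AlignmentResult:
    """Optimal alignment of the whole query to any target substring.

    Gotoh three-state dynamic programming with affine gaps. Target
    residues outside the aligned window cost nothing (free end gaps on
    the target); the query is consumed in full, gap columns included if
    they pay. Traceback ties prefer substitution, then query-residue-
    over-gap, then target-residue-over-gap, giving one deterministic
    optimum.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    n, m = len(query), len(target)
    go, ge = scheme.gap_open, scheme.gap_extend
    idx = scheme._index
    try:
        q = [idx[c] for c in query]
        t = [idx[c] for c in target]
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r}") from None
    mat = scheme.matrix

    # State D: column q[i-1]/t[j-1]; P: q[i-1]/'-'; Q: '-'/t[j-1].
    D = np.full((n + 1, m + 1), _NEG_INF)
    P = np.full((n + 1, m + 1), _NEG_INF)
    Q = np.full((n + 1, m + 1), _NEG_INF)
    # Pointer codes: source state 0=D, 1=P, 2=Q, 3=start.
    ptrD = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrP = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrQ = np.zeros((n + 1, m + 1), dtype=np.int8)

    D[0, :] = 0.0  # free leading target residues: start anywhere
    ptrD[0, :] = 3
    for i in range(1, n + 1):
        P[i, 0] = go + (i - 1) * ge
        ptrP[i, 0] = 3 if i == 1 else 1

    for i in range(1, n + 1):
        qi = q[i - 1]
        row = mat[qi]
        Dp, Pp, Qp = D[i - 1], P[i - 1], Q[i - 1]
        Di, Pi, Qi = D[i], P[i], Q[i]
        pD, pP, pQ = ptrD[i], ptrP[i], ptrQ[i]
        for j in range(1, m + 1):
            # substitution column
            a, b, c = Dp[j - 1], Pp[j - 1], Qp[j - 1]
            best, src = a, 0
            if b > best:
                best, src = b, 1
            if c > best:
                best, src = c, 2
            Di[j] = best + row[t[j - 1]]
            pD[j] = src
            # query residue over target gap
            a = Dp[j] + go
            b = Pp[j] + ge
            c = Qp[j] + go
            best, src = a, 0
            if b > best:
                best, src = b, 1
            if c > best:
                best, src = c, 2
            Pi[j] = best
            pP[j] = src
            # target residue over query gap (internal only: i >= 1)
            a = Di[j - 1] + go
            b = Pi[j - 1] + go
            c = Qi[j - 1] + ge
            best, src = a, 0
            if b > best:
                best, src = b, 1
            if c > best:
                best, src = c, 2
            Qi[j] = best
            pQ[j] = src

    # Free trailing target residues: end at any column of the last row.
    # A final Q column (target residue over gap) only lowers the score,
    # so the optimum ends in D or P; ties prefer D, then smaller j.
    best_score, best_j, best_state = _NEG_INF, 0, 0
    for j in range(m + 1):
        if D[n, j] > best_score:
            best_score, best_j, best_state = D[n, j], j, 0
    for j in range(m + 1):
        if P[n, j] > best_score:
            best_score, best_j, best_state = P[n, j], j, 1

    qa, ta = [], []
    i, j, state = n, best_j, best_state
    ptr = (ptrD, ptrP, ptrQ)
    while i > 0 or state != 0:
        src = ptr[state][i, j]
        if state == 0:
            qa.append(query[i - 1])
            ta.append(target[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            qa.append(query[i - 1])
            ta.append("-")
            i -= 1
        else:
            qa.append("-")
            ta.append(target[j - 1])
            j -= 1
        if src == 3:
            break
        state = src
    qa.reverse()
    ta.reverse()
    query_aln, target_aln = "".join(qa), "".join(ta)

    span = len(target_aln) - target_aln.count("-")
    target_end = best_j
    target_start = target_end - span + 1
    if span == 0:  # degenerate all-gap query (pathological scoring only)
        target_start, target_end = best_j + 1, best_j

    score = int(best_score)
    result = AlignmentResult(
        query_aln=query_aln,
        target_aln=target_aln,
        score=score,
        target_start=target_start,
        target_end=target_end,
        identity_percent=identity_degree((query_aln, target_aln)),
        evalue=None if evd is None else evalue(score, evd),
    )
    return result


def _draw_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    draws = rng.choice(20, size=length, p=probs)
    return "".join(AMINO_ACIDS[k] for k in draws)


def calibrate_evd(
    scheme: ScoringScheme,
    query: str,
    length_distribution,
    n_samples: int = 500,
    seed: int = 0,
    composition: np.ndarray | None = None,
    database_size: int = 1,
) -> EVDParams:
    """Fit the chance-score Gumbel by the method of moments.

    Aligns the query against ``n_samples`` random sequences (uniform
    residue composition unless given) and matches the sample mean and
    variance to the Gumbel mean ``mu + gamma*beta`` and variance
    ``(pi*beta)^2 / 6``. ``length_distribution`` is either a fixed int,
    a ``(mean, sd)`` pair for a truncated normal (floored at the query
    length), or a callable ``rng -> int``.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100 for a stable fit")
    rng = np.random.default_rng(seed)
    if composition is None:
        probs = np.full(20, 1.0 / 20.0)
    else:
        probs = np.asarray(composition, dtype=float)
        probs = probs / probs.sum()

    if callable(length_distribution):
        draw_len = length_distribution
    elif isinstance(length_distribution, (int, np.integer)):
        fixed = int(length_distribution)
        draw_len = lambda r: fixed
    else:
        mean, sd = length_distribution
        draw_len = lambda r: max(len(query), int(round(r.normal(mean, sd))))

    scores = np.empty(n_samples)
    for k in range(n_samples):
        length = max(len(query), int(draw_len(rng)))
        seq = _draw_sequence(rng, length, probs)
        scores[k] = align_glocal(query, seq, scheme).score

    var = scores.var(ddof=1)
    if var == 0:
        raise ValueError("degenerate score sample: zero variance")
    beta = math.sqrt(6.0 * var) / math.pi
    mu = scores.mean() - _EULER_GAMMA * beta
    return EVDParams(mu=mu, beta=beta, database_size=database_size)


def evalue(score: float, params: EVDParams) -> float:
    """Expected count of chance alignments scoring >= ``score``.

    ``E = database_size * (1 - exp(-exp(-(score - mu)/beta)))``, clipped
    to ``[0, database_size]``; strictly decreasing in the score.
    """
    z = (score - params.mu) / params.beta
    # per-sequence upper-tail probability of the Gumbel
    if z > 35:  # exp(-z) underflows the double-exponential gracefully
        p = math.exp(-z)
    else:
        p = -math.expm1(-math.exp(-z))
    e = params.database_size * p
    return min(max(e, 0.0), float(params.database_size))


def with_database_size(params: EVDParams, database_size: int) -> EVDParams:
    """Same Gumbel, rescaled to a database of ``database_size`` records."""
    return replace(params, database_size=database_size)
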