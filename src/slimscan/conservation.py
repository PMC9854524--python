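"""Per-position conservation statistics for a unique-motif set.

Given equal-length, gap-free motifs the module computes the position
frequency matrix (percent of motifs carrying each residue at each
position, ``N = a/b * 100`` with ``a`` the residue count and ``b`` the
motif total), renders a consensus notation such as
``L[MIV]D[NE]S[TKE]Y[F]Q[KDR]CT[S]`` (major residue plus bracketed
alternates at or above a frequency threshold), and derives sequence-logo
columns (information content in bits and per-residue stack heights).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AMINO_ACIDS
from .motif_search import MotifSet

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_LOG2_20 = math.log2(20)

__all__ = [
    "PositionFrequencyMatrix",
    "ConsensusSpec",
    "LogoColumn",
    "position_frequencies",
    "consensus_notation",
    "parse_consensus",
    "logo_columns",
]


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """L x 20 percentage matrix plus the motif count it was built from."""

    freq: np.ndarray  # percentages, rows = positions, cols = AMINO_ACIDS
    b: int  # number of motifs counted

    def __post_init__(self):
        if self.freq.ndim != 2 or self.freq.shape[1] != 20:
            raise ValueError("freq must be an L x 20 matrix")
        if (self.freq < 0).any():
            raise ValueError("frequencies must be non-negative")
        if not np.allclose(self.freq.sum(axis=1), 100.0, atol=1e-9):
            raise ValueError("each position must sum to 100%")

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq, columns=list(AMINO_ACIDS))
        df.insert(0, "position", np.arange(1, self.length + 1))
        return df


@dataclass(frozen=True)
class ConsensusSpec:
    """Major residue and ordered alternates per position."""

    positions: tuple[tuple[str, tuple[str, ...]], ...]
    notation: str

    def __post_init__(self):
        for major, alts in self.positions:
            if major in alts:
                raise ValueError("major residue repeated in alternates")


@dataclass(frozen=True)
class LogoColumn:
    """One sequence-logo stack: total bits and per-residue heights."""

    information_content: float
    symbol_heights: dict
    small_sample_corrected: bool

    def __post_init__(self):
        if self.information_content > _LOG2_20 + 1e-12:
            raise ValueError("information content cannot exceed log2(20)")
        if any(h < 0 for h in self.symbol_heights.values()):
            raise ValueError("stack heights must be non-negative")


def position_frequencies(motifs) -> PositionFrequencyMatrix:
    """Count residues per position: ``freq[p][r] = 100 * a / b``.

    Accepts a MotifSet or any iterable of equal-length gap-free motif
    strings. Motifs containing X are excluded (with a warning) since X
    is not one of the 20 logo residues; ragged lengths are an error.
    """
    if isinstance(motifs, MotifSet):
        seqs = list(motifs.motifs)
    else:
        seqs = list(motifs)
    kept = [m for m in seqs if "X" not in m]
    if len(kept) < len(seqs):
        logger.warning(
            "%d motif(s) containing X excluded from frequency counting",
            len(seqs) - len(kept),
        )
    if not kept:
        raise ValueError("no motifs to count")
    length = len(kept[0])
    if any(len(m) != length for m in kept):
        raise ValueError("motifs must all have the same length")
    counts = np.zeros((length, 20))
    for m in kept:
        for p, aa in enumerate(m):
            counts[p, _AA_INDEX[aa]] += 1
    return PositionFrequencyMatrix(freq=100.0 * counts / len(kept), b=len(kept))


def consensus_notation(
    pfm: PositionFrequencyMatrix, alt_threshold: float = 5.0
) -> ConsensusSpec:
    """Build the consensus string from a PFM.

    Per position the major residue is the frequency argmax (ties broken
    alphabetically, logged); alternates are every other residue at or
    above ``alt_threshold`` percent, in descending frequency (frequency
    ties alphabetical). Brackets are omitted when no alternate passes.
    """
    if not (0 < alt_threshold < 100):
        raise ValueError("alt_threshold must be within (0, 100)")
    positions = []
    parts = []
    for p in range(pfm.length):
        row = pfm.freq[p]
        top = row.max()
        tied = [AMINO_ACIDS[i] for i in np.flatnonzero(row == top)]
        major = min(tied)
        if len(tied) > 1:
            logger.info(
                "position %d: tie for major residue among %s; chose %s",
                p + 1, tied, major,
            )
        alts = [
            aa
            for aa in sorted(AMINO_ACIDS, key=lambda a: (-row[_AA_INDEX[a]], a))
            if aa != major and row[_AA_INDEX[aa]] >= alt_threshold
        ]
        positions.append((major, tuple(alts)))
        parts.append(major + (f"[{''.join(alts)}]" if alts else ""))
    return ConsensusSpec(positions=tuple(positions), notation="".join(parts))


_CONSENSUS_RE = re.compile(r"([A-Z])(?:\[([A-Z]+)\])?")


def parse_consensus(notation: str) -> tuple[tuple[str, tuple[str, ...]], ...]:
    """Inverse of consensus_notation's string rendering."""
    out, pos = [], 0
    for m in _CONSENSUS_RE.finditer(notation):
        if m.start() != pos:
            raise ValueError(f"malformed consensus notation: {notation!r}")
        out.append((m.group(1), tuple(m.group(2) or "")))
        pos = m.end()
    if pos != len(notation) or not out:
        raise ValueError(f"malformed consensus notation: {notation!r}")
    return tuple(out)


def logo_columns(
    pfm: PositionFrequencyMatrix, corrected: bool = True
) -> list[LogoColumn]:
    """Sequence-logo information content per position.

    ``IC = log2(20) - H - e_n`` with ``H`` the Shannon entropy of the
    position's residue frequencies and ``e_n = 19 / (2 ln2 b)`` the
    small-sample correction (applied when ``corrected``), floored at 0.
    Residue stack height is frequency times IC.
    """
    correction = (20 - 1) / (2 * math.log(2) * pfm.b) if corrected else 0.0
    columns = []
    for p in range(pfm.length):
        f = pfm.freq[p] / 100.0
        nz = f[f > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        ic = max(_LOG2_20 - entropy - correction, 0.0)
        heights = {
            AMINO_ACIDS[i]: float(f[i] * ic) for i in range(20) if f[i] > 0
        }
        columns.append(
            LogoColumn(
                information_content=ic,
                symbol_heights=heights,
                small_sample_corrected=corrected,
            )
        )
    return columns
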