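"""Low-level nucleotide utilities shared across the pipeline.

Sequences are plain uppercase ``str`` throughout the package; these helpers
centralise the IUPAC degeneracy tables (including inosine, written ``I``,
which base-pairs indiscriminately) and the alignment-identity definition used
by clustering and best-hit classification.
"""

from __future__ import annotations

import numpy as np
from Bio import Align

# 4-bit encoding: one bit per canonical base, degenerate codes are unions.
_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
    "I": 15,  # inosine pairs with any base
}

IUPAC_ALPHABET = frozenset(_BITS)
CANONICAL = frozenset("ACGT")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNI",
    "TGCAYRSWMKVHDBNI",
)

_BIT_LUT = np.zeros(256, dtype=np.uint8)
for _c, _b in _BITS.items():
    _BIT_LUT[ord(_c)] = _b
    _BIT_LUT[ord(_c.lower())] = _b


def revcomp(seq: str) -> str:
    """Reverse complement; degenerate codes map to their complements, I -> I."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Byte view of a sequence for vectorised comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def encode_bits(seq: str) -> np.ndarray:
    """IUPAC bitmask encoding; unknown characters encode to 0 (match nothing)."""
    return _BIT_LUT[encode(seq)]


def hamming(a: str, b: str) -> int:
    """Number of differing positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return int(np.count_nonzero(encode(a) != encode(b)))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner

_ALIGNER = _make_aligner()


def global_alignment(a: str, b: str):
    """Highest-scoring global alignment under the package-wide scoring
    (match +1, mismatch -1, gap open -2, gap extend -1)."""
    return _ALIGNER.align(a, b)[0]


def alignment_identity(a: str, b: str) -> float:
    """Fraction of identical columns over all columns (gap columns included)
    of the optimal global alignment.

    For equal-length near-identical inputs the ungapped alignment is optimal,
    so a cheap Hamming screen short-circuits the dynamic programming.
    """
    if a == b:
        return 1.0
    if len(a) == len(b):
        mism = hamming(a, b)
        # Gaps in equal-length sequences come in pairs costing >= 2 opens;
        # with this few substitutions the ungapped alignment is optimal.
        if mism / len(a) <= 0.05:
            return 1.0 - mism / len(a)
    counts = global_alignment(a, b).counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns
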