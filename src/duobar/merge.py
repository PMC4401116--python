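"""Paired-end read merging by ungapped overlap, with quality/length gates.

The merger scans every ungapped overlap between the forward read and the
reverse-complemented reverse read, from the longest down to the configured
minimum, and accepts the first whose mismatch fraction is within budget
(longest-first with first-accept is the deterministic tie-break). Consensus
at an agreeing column keeps the base with quality ``max(q1, q2)``; at a
disagreeing column it keeps the higher-quality base with quality
``|q1 - q2|``, the usual read-merger convention for conflicting evidence.

The Phred-20 threshold is applied as a mean-quality filter on the merged
read (:func:`quality_gate`), the least destructive reading of a minimum-
quality requirement; per-base trimming is deliberately not performed.
Fragment-specific length windows (:func:`length_gate`) police the merged
product: 300-400 nt for FC, 400-500 nt for BR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, revcomp
from .io import Read, ReadPair
from .demux import DemuxRecord

__all__ = ["MergeConfig", "MergedRead", "merge_pair", "quality_gate", "length_gate"]


@dataclass(frozen=True)
class MergeConfig:
    """Merging and filtering thresholds (defaults are the pipeline standard)."""

    min_overlap: int = 25
    min_mean_phred: int = 20
    max_overlap_mismatch_frac: float = 0.02
    fc_length: tuple[int, int] = (300, 400)
    br_length: tuple[int, int] = (400, 500)

    def __post_init__(self) -> None:
        if self.min_overlap <= 0:
            raise ValueError("min_overlap must be positive")
        if not 0 <= self.max_overlap_mismatch_frac <= 1:
            raise ValueError("max_overlap_mismatch_frac must lie in [0, 1]")
        for lo, hi in (self.fc_length, self.br_length):
            if lo > hi:
                raise ValueError("empty length interval")

    def length_window(self, fragment: str) -> tuple[int, int]:
        if fragment == "FC":
            return self.fc_length
        if fragment == "BR":
            return self.br_length
        raise ValueError(f"unknown fragment {fragment!r}")


@dataclass
class MergedRead:
    read: Read
    overlap_length: int
    mismatches_in_overlap: int


def merge_pair(pair: ReadPair, cfg: MergeConfig = MergeConfig()) -> MergedRead | None:
    """Merge one read pair, or return ``None`` if no overlap qualifies."""
    fwd = pair.forward
    rc_seq = revcomp(pair.reverse.sequence)
    rc_qual = np.array(pair.reverse.qualities[::-1], dtype=np.int32)
    f = encode(fwd.sequence)
    r = encode(rc_seq)
    fq = np.array(fwd.qualities, dtype=np.int32)
    nf, nr = len(f), len(r)

    for olap in range(min(nf, nr), cfg.min_overlap - 1, -1):
        a = f[nf - olap:]
        b = r[:olap]
        mismatch_mask = a != b
        mism = int(np.count_nonzero(mismatch_mask))
        if mism > cfg.max_overlap_mismatch_frac * olap:
            continue
        qa = fq[nf - olap:]
        qb = rc_qual[:olap]
        # Forward base wins quality ties at disagreements (deterministic).
        take_b = mismatch_mask & (qb > qa)
        cons = np.where(take_b, b, a)
        cons_q = np.where(mismatch_mask, np.abs(qa - qb), np.maximum(qa, qb))
        seq = fwd.sequence[: nf - olap] + cons.tobytes().decode("ascii") + rc_seq[olap:]
        quals = (list(fwd.qualities[: nf - olap]) + [int(q) for q in cons_q]
                 + [int(q) for q in rc_qual[olap:]])
        merged = Read(id=fwd.id, sequence=seq, qualities=quals)
        return MergedRead(read=merged, overlap_length=olap, mismatches_in_overlap=mism)
    return None


def quality_gate(merged: MergedRead, cfg: MergeConfig = MergeConfig()) -> bool:
    """Keep iff the mean Phred quality of the merged read is >= the minimum."""
    return float(np.mean(merged.read.qualities)) >= cfg.min_mean_phred


def length_gate(item, cfg: MergeConfig = MergeConfig(), fragment: str | None = None) -> bool:
    """Keep iff the (merged read or insert) length lies in the closed window
    for its fragment.

    ``item`` may be a :class:`~duobar.demux.DemuxRecord` (fragment and insert
    taken from it), a :class:`MergedRead`/:class:`~duobar.io.Read` (pass
    ``fragment``), or a plain length.
    """
    if isinstance(item, DemuxRecord):
        n = len(item.insert)
        fragment = item.fragment
    elif isinstance(item, MergedRead):
        n = len(item.read)
    elif isinstance(item, Read):
        n = len(item)
    elif isinstance(item, int):
        n = item
    else:
        raise TypeError(f"cannot take a length from {type(item).__name__}")
    if fragment is None:
        raise ValueError("fragment must be given when item does not carry one")
    lo, hi = cfg.length_window(fragment)
    return lo <= n <= hi
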