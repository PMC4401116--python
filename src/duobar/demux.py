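"""Well assignment from terminal 5-mer MIDs, plus MID/primer trimming.

A merged amplicon read has the layout::

    [forward MID][forward primer][insert][revcomp(reverse primer)][revcomp(reverse MID)]

Demultiplexing reads the first and last 5 nt (the latter reverse-
complemented), looks the pair up in the tag map, and trims MIDs and primers
to recover the insert. Both read orientations are tried; a read whose two
orientations both resolve to a tag combination is ambiguous and left
unassigned. MID matching is exact by default — a single error in a 5-mer
cannot be corrected safely against a 20-MID list.

Primers may contain IUPAC degeneracies and inosine (``I``), which matches
any base; they are located with a bounded mismatch budget inside a short
window just inward of each MID, so that a degenerate primer is still found
after PCR/sequencing error without risking internal false hits. Reads whose
MIDs resolve but whose primers cannot be located are kept with MID-only
trimming and counted, leaving the downstream length gates to police them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import encode_bits, revcomp
from .io import Read, WellAssignment

__all__ = [
    "PrimerSet", "DemuxRecord", "DemuxStats",
    "match_degenerate", "Demultiplexer",
]

#: Published fragment-internal primers (5'->3'). The outer primers of the
#: two fragments are standard COI barcoding primers supplied by the caller.
ILL_C_R = "GGIGGRTAIACIGTTCAICC"
ILL_B_F = "CCIGAYATRGCITTYCCICG"


@dataclass(frozen=True)
class PrimerSet:
    """The four amplification primers, one pair per fragment.

    ``fc_forward`` and ``br_reverse`` are the outer (LCO1490/HCO2198-style)
    primers and must be supplied by the caller; the two fragment-internal
    primers default to the published sequences.
    """

    fc_forward: str
    br_reverse: str
    fc_reverse: str = ILL_C_R
    br_forward: str = ILL_B_F

    def __post_init__(self) -> None:
        for name in ("fc_forward", "fc_reverse", "br_forward", "br_reverse"):
            primer = getattr(self, name)
            if not primer:
                raise ValueError(f"{name}: empty primer")
            if np.any(encode_bits(primer) == 0):
                raise ValueError(f"{name}: non-IUPAC characters in {primer!r}")

    def pair_for(self, fragment: str) -> tuple[str, str]:
        if fragment == "FC":
            return self.fc_forward, self.fc_reverse
        if fragment == "BR":
            return self.br_forward, self.br_reverse
        raise ValueError(f"unknown fragment {fragment!r}")


@dataclass
class DemuxRecord:
    """One read assigned to a plate/well/fragment, trimmed to its insert."""

    read_id: str
    plate: str
    well: str
    fragment: str
    insert: str

    @property
    def specimen(self) -> str:
        return f"{self.plate}_{self.well}"


@dataclass
class DemuxStats:
    total: int = 0
    assigned: int = 0
    unassigned_no_tag: int = 0
    unassigned_ambiguous: int = 0
    unassigned_empty_insert: int = 0
    primer_not_found: int = 0  # assigned reads trimmed by MIDs only

    @property
    def unassigned(self) -> int:
        return (self.unassigned_no_tag + self.unassigned_ambiguous
                + self.unassigned_empty_insert)


def match_degenerate(primer: str, window: str, max_mismatch: int = 0) -> int | None:
    """Leftmost offset at which ``primer`` matches inside ``window`` with at
    most ``max_mismatch`` mismatches, or ``None``.

    Degenerate IUPAC positions match their base sets; ``I`` and ``N`` match
    anything (on either side of the comparison).
    """
    p = encode_bits(primer)
    w = encode_bits(window)
    k = len(p)
    if len(w) < k:
        raise ValueError("window shorter than primer")
    for offset in range(len(w) - k + 1):
        mism = int(np.count_nonzero((p & w[offset:offset + k]) == 0))
        if mism <= max_mismatch:
            return offset
    return None


class Demultiplexer:
    """Assigns merged reads to wells via an indexed tag map.

    Parameters
    ----------
    assignments:
        Tag map rows, typically for one plate pool. Forward/reverse MID
        combinations must be unique.
    primers:
        The :class:`PrimerSet` used to trim primer sequence off the insert.
    mid_mismatch:
        Mismatches tolerated when matching each terminal 5-mer (default 0).
    primer_window:
        How far inward of a MID the primer start may drift (nt).
    primer_max_mismatch:
        Mismatch budget for locating each (degenerate) primer.
    """

    MID_LEN = 5

    def __init__(
        self,
        assignments: list[WellAssignment],
        primers: PrimerSet,
        mid_mismatch: int = 0,
        primer_window: int = 30,
        primer_max_mismatch: int = 2,
    ) -> None:
        self.primers = primers
        self.mid_mismatch = mid_mismatch
        self.primer_window = primer_window
        self.primer_max_mismatch = primer_max_mismatch
        self.stats = DemuxStats()
        self._index: dict[tuple[str, str], WellAssignment] = {}
        for wa in assignments:
            key = (wa.forward_mid, wa.reverse_mid)
            if key in self._index:
                raise ValueError(f"ambiguous tag combination {key} in mapping")
            self._index[key] = wa

    def _lookup(self, seq: str) -> WellAssignment | None:
        n = self.MID_LEN
        if len(seq) < 2 * n + 1:
            return None
        fwd, rev = seq[:n], revcomp(seq[-n:])
        if self.mid_mismatch == 0:
            return self._index.get((fwd, rev))
        hits = [
            wa for (f, r), wa in self._index.items()
            if sum(a != b for a, b in zip(f, fwd)) <= self.mid_mismatch
            and sum(a != b for a, b in zip(r, rev)) <= self.mid_mismatch
        ]
        return hits[0] if len(hits) == 1 else None

    def _trim(self, seq: str, wa: WellAssignment) -> str | None:
        """Strip MIDs and primers; None means the insert vanished."""
        core = seq[self.MID_LEN:-self.MID_LEN]
        fwd_primer, rev_primer = self.primers.pair_for(wa.fragment)
        found_both = True

        window = core[: len(fwd_primer) + self.primer_window]
        off = (match_degenerate(fwd_primer, window, self.primer_max_mismatch)
               if len(window) >= len(fwd_primer) else None)
        if off is not None:
            core = core[off + len(fwd_primer):]
        else:
            found_both = False

        tail = revcomp(core)[: len(rev_primer) + self.primer_window]
        off = (match_degenerate(rev_primer, tail, self.primer_max_mismatch)
               if len(tail) >= len(rev_primer) else None)
        if off is not None:
            core = core[: len(core) - off - len(rev_primer)]
        else:
            found_both = False

        if not found_both:
            self.stats.primer_not_found += 1
        return core or None

    def assign(self, merged: Read) -> DemuxRecord | None:
        """Assign one merged read, or return ``None`` (unassigned).

        Unassigned reads are tallied in :attr:`stats` by reason.
        """
        self.stats.total += 1
        seq = merged.sequence
        hit_fwd = self._lookup(seq)
        rc = revcomp(seq)
        hit_rev = self._lookup(rc)
        if hit_fwd is not None and hit_rev is not None:
            self.stats.unassigned_ambiguous += 1
            return None
        if hit_fwd is None and hit_rev is None:
            self.stats.unassigned_no_tag += 1
            return None
        wa, oriented = (hit_fwd, seq) if hit_fwd is not None else (hit_rev, rc)
        insert = self._trim(oriented, wa)
        if insert is None:
            self.stats.unassigned_empty_insert += 1
            return None
        self.stats.assigned += 1
        return DemuxRecord(
            read_id=merged.id, plate=wa.plate, well=wa.well,
            fragment=wa.fragment, insert=insert,
        )

    def assign_all(self, reads) -> list[DemuxRecord]:
        return [rec for read in reads if (rec := self.assign(read)) is not None]
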