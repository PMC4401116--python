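"""Readers and writers for the formats the pipeline touches.

FASTQ is 4-line Phred+33 (the MiSeq default); other offsets are rejected
rather than guessed. The tag-mapping table is a plain TSV with a header:
``plate  well  fragment  forward_mid  reverse_mid``. All file arguments
accept plain or gzip-compressed paths.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import IUPAC_ALPHABET

__all__ = [
    "Read", "ReadPair", "MidTable", "WellAssignment",
    "FC_MIDS", "BR_MIDS",
    "read_fastq", "write_fastq", "read_fasta", "write_fasta",
    "load_mapping", "write_mapping", "ParseError",
]

#: The two published 20-entry lists of 5-mer multiple identifiers (MIDs),
#: one list per amplicon fragment. Both ends of an amplicon carry a MID
#: drawn from its fragment's list.
FC_MIDS: tuple[str, ...] = (
    "AAGCT", "ATTGC", "AGATC", "AGCAT", "TTCAG", "TGATC", "TCAAG", "TGAGC",
    "CAATG", "CATTG", "CTTGA", "CTGAA", "ATGCA", "AGCTT", "TGCAA", "TGCCA",
    "TCATG", "CATGA", "CTGAT", "CATGC",
)
BR_MIDS: tuple[str, ...] = (
    "ATGCT", "ATGCC", "AGCTG", "AGCTC", "TGCAT", "TGCAG", "TCAGA", "TCAGG",
    "CAGAT", "CCTGA", "CTCAG", "CTGCA", "ATCAG", "AGCCT", "ATCTG", "TCAGC",
    "TCTGA", "TCCAG", "CAGCT", "CTGAG",
)

_WELL_RE = re.compile(r"^[A-H](1[0-2]|[1-9])$")


class ParseError(ValueError):
    """Raised for malformed input files, naming the offending record."""


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        bad = set(self.sequence) - IUPAC_ALPHABET
        if bad:
            raise ValueError(f"read {self.id!r}: non-IUPAC characters {sorted(bad)}")
        if any(q < 0 or q > 93 for q in self.qualities):
            raise ValueError(f"read {self.id!r}: Phred score outside [0, 93]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadPair:
    """Forward/reverse mates of one paired-end read."""

    forward: Read
    reverse: Read


@dataclass(frozen=True)
class MidTable:
    """The dual 5-mer index design: 20 MIDs per fragment, 40 in total."""

    fc_mids: tuple[str, ...] = FC_MIDS
    br_mids: tuple[str, ...] = BR_MIDS

    def __post_init__(self) -> None:
        all_mids = self.fc_mids + self.br_mids
        if len(all_mids) != 40 or len(set(all_mids)) != 40:
            raise ValueError("MID table must hold exactly 40 mutually distinct MIDs")
        for mid in all_mids:
            if len(mid) != 5 or set(mid) - set("ACGT"):
                raise ValueError(f"invalid MID {mid!r}: must be a 5-mer over ACGT")

    def mids_for(self, fragment: str) -> tuple[str, ...]:
        if fragment == "FC":
            return self.fc_mids
        if fragment == "BR":
            return self.br_mids
        raise ValueError(f"unknown fragment {fragment!r}")


@dataclass(frozen=True)
class WellAssignment:
    """Maps one (fragment, forward MID, reverse MID) combination to a well."""

    plate: str
    well: str
    fragment: str  # "FC" or "BR"
    forward_mid: str
    reverse_mid: str

    def __post_init__(self) -> None:
        if self.fragment not in ("FC", "BR"):
            raise ValueError(f"fragment must be FC or BR, got {self.fragment!r}")
        if not _WELL_RE.match(self.well):
            raise ValueError(f"well {self.well!r} not in A1..H12")

    @property
    def specimen(self) -> str:
        return f"{self.plate}_{self.well}"


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[Read]:
    """Stream reads from a 4-line Phred+33 FASTQ file (plain or .gz).

    Sequences are uppercased on read. Malformed records raise
    :class:`ParseError` naming the record.
    """
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                yield Read(
                    id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=list(rec.letter_annotations["phred_quality"]),
                )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[Read], path) -> None:
    with _open_text(path, "wt") as handle:
        for read in reads:
            rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
            rec.letter_annotations["phred_quality"] = read.qualities
            SeqIO.write(rec, handle, "fastq")


def read_fasta(path) -> list[tuple[str, str]]:
    """Return ``(id, uppercased sequence)`` pairs from a FASTA file."""
    with _open_text(path) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    """Write ``(id, sequence)`` pairs as FASTA. Duplicate ids are an error."""
    records = list(records)
    seen: set[str] = set()
    for rid, _ in records:
        if rid in seen:
            raise ValueError(f"duplicate FASTA id {rid!r}")
        seen.add(rid)
    with _open_text(path, "wt") as handle:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records),
            handle,
            "fasta",
        )


_MAPPING_COLUMNS = ["plate", "well", "fragment", "forward_mid", "reverse_mid"]


def load_mapping(path, mids: MidTable | None = None) -> list[WellAssignment]:
    """Load the tag-mapping TSV and validate it against the MID table.

    Every MID must come from its fragment's list and each
    (plate, fragment, forward MID, reverse MID) combination must be unique —
    otherwise demultiplexing would be ambiguous.
    """
    mids = mids or MidTable()
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_MAPPING_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing mapping columns {sorted(missing)}")
    assignments = []
    seen: set[tuple[str, str, str, str]] = set()
    for row in df.itertuples(index=False):
        wa = WellAssignment(
            plate=row.plate, well=row.well, fragment=row.fragment,
            forward_mid=row.forward_mid.upper(), reverse_mid=row.reverse_mid.upper(),
        )
        allowed = mids.mids_for(wa.fragment)
        for mid in (wa.forward_mid, wa.reverse_mid):
            if mid not in allowed:
                raise ParseError(
                    f"{path}: MID {mid!r} not in the {wa.fragment} MID list"
                )
        key = (wa.plate, wa.fragment, wa.forward_mid, wa.reverse_mid)
        if key in seen:
            raise ParseError(f"{path}: duplicate tag combination {key}")
        seen.add(key)
        assignments.append(wa)
    return assignments


def write_mapping(assignments: Iterable[WellAssignment], path) -> None:
    df = pd.DataFrame(
        [(a.plate, a.well, a.fragment, a.forward_mid, a.reverse_mid)
         for a in assignments],
        columns=_MAPPING_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
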