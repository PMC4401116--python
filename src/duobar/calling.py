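"""Per-specimen barcode calling, best-hit identification, and concordance.

A specimen's assembled barcodes are filtered by the abundance rule: a
sequence is reported only when its support is strictly greater than 10% of
the specimen's total support (support of an assembly = the smaller of its
two fragment-cluster sizes). With a 10% floor a specimen can report at most
nine sequences; in practice a handful — the dominant true barcode plus any
abundant co-amplified contaminant or endosymbiont.

Identification is a local best-hit search against a labelled reference
FASTA: the reported label is that of the reference with the highest global
alignment identity (ties go to the earlier reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._seq import alignment_identity, CANONICAL
from .io import read_fasta
from .pairing import AssembledBarcode

__all__ = [
    "CalledSequence", "BarcodeRecord", "ReferenceDb",
    "call_barcodes", "best_hit", "identify", "concordance_table",
]


@dataclass
class CalledSequence:
    sequence: str
    abundance_fraction: float
    label: str | None = None
    identity: float | None = None


@dataclass
class BarcodeRecord:
    """The outcome of barcode calling for one specimen."""

    specimen: str | None
    sequences: list[CalledSequence]
    status: str  # "none" | "single" | "multiple"


@dataclass
class ReferenceDb:
    """A labelled reference set standing in for a public barcode database."""

    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if any(not label or not seq for label, seq in self.records):
            raise ValueError("reference records need non-empty labels and sequences")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceDb":
        return cls(records=read_fasta(path))

    def __len__(self) -> int:
        return len(self.records)


def call_barcodes(
    assembled: Sequence[AssembledBarcode],
    min_frac: float = 0.10,
    specimen: str | None = None,
) -> BarcodeRecord:
    """Apply the strict >``min_frac`` abundance rule to one specimen.

    Reported sequences are ordered by descending abundance fraction; the
    record status reflects how many survive (none/single/multiple).
    """
    if specimen is None and assembled:
        specimen = assembled[0].specimen
    total = sum(a.support for a in assembled)
    sequences: list[CalledSequence] = []
    if total > 0:
        for a in sorted(assembled, key=lambda a: (-a.support, a.sequence)):
            frac = a.support / total
            if frac > min_frac:
                sequences.append(CalledSequence(sequence=a.sequence,
                                                abundance_fraction=frac))
    status = "none" if not sequences else ("single" if len(sequences) == 1
                                           else "multiple")
    return BarcodeRecord(specimen=specimen, sequences=sequences, status=status)


def best_hit(seq: str, db: ReferenceDb) -> tuple[str, float]:
    """Label and identity of the reference closest to ``seq``.

    Identity is global alignment identity under the package-wide scoring;
    ties are broken by database order.
    """
    if not len(db):
        raise ValueError("empty reference database")
    best_label, best_id = None, -1.0
    for label, ref in db.records:
        ident = alignment_identity(seq, ref)
        if ident > best_id:
            best_label, best_id = label, ident
    return best_label, best_id


def identify(records: Iterable[BarcodeRecord], db: ReferenceDb) -> None:
    """Annotate every reported sequence in-place with its best hit."""
    for rec in records:
        for cs in rec.sequences:
            cs.label, cs.identity = best_hit(cs.sequence, db)


def _looks_like_sequence(value: str) -> bool:
    return len(value) >= 30 and set(value.upper()) <= (CANONICAL | {"N"})


def concordance_table(
    records: Sequence[BarcodeRecord],
    truth: Mapping[str, str],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Compare called barcodes against per-specimen expectations.

    ``truth`` maps specimen -> expected taxon label, or expected sequence
    (detected by alphabet); labels compare against the top-ranked called
    sequence's best-hit label, sequences against the top-ranked called
    sequence itself (exact match). Per-specimen statuses are ``match``,
    ``non_match``, ``no_sequence`` and — for specimens missing from the
    truth map — ``no_expectation``, which is excluded from percentages.
    """
    rows = []
    for rec in records:
        if rec.specimen not in truth:
            status = "no_expectation"
            expected = None
        elif not rec.sequences:
            status = "no_sequence"
            expected = truth[rec.specimen]
        else:
            expected = truth[rec.specimen]
            top = rec.sequences[0]
            if _looks_like_sequence(expected):
                ok = top.sequence == expected.upper()
            else:
                ok = top.label == expected
            status = "match" if ok else "non_match"
        rows.append({"specimen": rec.specimen, "status": status,
                     "expected": expected})
    df = pd.DataFrame(rows, columns=["specimen", "status", "expected"])
    counts = df["status"].value_counts().to_dict()
    summary = {s: int(counts.get(s, 0))
               for s in ("match", "non_match", "no_sequence", "no_expectation")}
    evaluable = summary["match"] + summary["non_match"] + summary["no_sequence"]
    summary["evaluable"] = evaluable
    summary["match_pct"] = round(100.0 * summary["match"] / evaluable, 1) if evaluable else 0.0
    return df, summary
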