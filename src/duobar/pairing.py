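"""Screening and assembly of FC x BR cluster pairs into full-length barcodes.

The two amplicon fragments of a specimen overlap (by design, 82 nt for the
default COI geometry). A FC/BR cluster pair is first *screened* for
compatibility: the highest-scoring ungapped local segment pair (HSP) between
the two centroids must reach 98% identity, span at least 25 nt, and carry at
most 2 mismatches. Both orientations of the BR centroid are tried. Screened
pairs are then *assembled* through their suffix/prefix overlap, requiring at
least 80 nt of overlap with at most a 2% mismatch fraction; the consensus at
an overlap mismatch takes the base from the larger cluster (FC on ties).

The HSP search is an exhaustive diagonal scan (every ungapped offset between
the two sequences, best-scoring run per diagonal via a vectorised Kadane
pass, match +1 / mismatch -2), so it IS the brute-force answer rather than a
heuristic approximation of one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import encode, revcomp
from .cluster import Cluster

__all__ = ["HspResult", "AssembledBarcode", "screen_pair", "assemble", "pair_specimen"]

_MATCH = 1
_MISMATCH = -2


@dataclass
class HspResult:
    """Best ungapped local segment pair between two centroids."""

    length: int
    identity: float
    mismatches: int
    fc_offset: int
    br_offset: int
    br_revcomp: bool  # True when the BR centroid matched in reverse complement


@dataclass
class AssembledBarcode:
    """A full-length barcode assembled from one FC and one BR cluster."""

    specimen: str | None
    sequence: str
    overlap_length: int
    fc_size: int
    br_size: int

    @property
    def support(self) -> int:
        return min(self.fc_size, self.br_size)


def _centroid(x) -> str:
    return x.centroid if isinstance(x, Cluster) else x


def _best_diagonal_hsp(a: np.ndarray, b: np.ndarray):
    """Highest-scoring ungapped segment over all diagonals.

    Returns (score, length, mismatches, a_start, b_start) or None. Ties
    break toward longer segments, then lower offsets (scan order).
    """
    na, nb = len(a), len(b)
    best = None
    for d in range(-(nb - 1), na):
        i0 = max(0, d)
        j0 = i0 - d
        n = min(na - i0, nb - j0)
        eq = a[i0:i0 + n] == b[j0:j0 + n]
        scores = np.where(eq, _MATCH, _MISMATCH)
        prefix = np.concatenate([[0], np.cumsum(scores)])
        pm = prefix[:-1]
        run_min = np.minimum.accumulate(pm)
        # index of the FIRST running minimum (gives the longest segment)
        idx = np.arange(n)
        new_min = np.concatenate([[True], pm[1:] < run_min[:-1]])
        first_min_idx = np.maximum.accumulate(np.where(new_min, idx, 0))
        gains = prefix[1:] - run_min
        if gains.max() <= 0:
            continue
        starts = first_min_idx
        lengths = idx + 1 - starts
        # best end by (score desc, length desc, start asc)
        order = np.lexsort((starts, -lengths, -gains))
        end = int(order[0])
        score = int(gains[end])
        start = int(starts[end])
        length = end + 1 - start
        matches = int(np.count_nonzero(eq[start:end + 1]))
        mism = length - matches
        cand = (score, length, -(i0 + start), -(j0 + start))
        if best is None or cand > best[0]:
            best = (cand, length, mism, i0 + start, j0 + start, score)
    if best is None:
        return None
    _, length, mism, a_start, b_start, score = best
    return score, length, mism, a_start, b_start


def screen_pair(
    fc, br,
    min_identity: float = 0.98,
    min_len: int = 25,
    max_mismatch: int = 2,
) -> HspResult | None:
    """Compatibility screen between a FC and a BR cluster (or raw strings).

    Finds the best ungapped HSP in either orientation of BR and accepts it
    iff identity >= ``min_identity``, length >= ``min_len`` and mismatches
    <= ``max_mismatch``; returns ``None`` (incompatible) otherwise.
    """
    fc_seq = _centroid(fc)
    br_seq = _centroid(br)
    if not fc_seq or not br_seq:
        raise ValueError("empty centroid")
    a = encode(fc_seq)
    best = None
    for is_rc, oriented in ((False, br_seq), (True, revcomp(br_seq))):
        hit = _best_diagonal_hsp(a, encode(oriented))
        if hit is None:
            continue
        score, length, mism, a_start, b_start = hit
        if best is None or (score, length) > (best[0], best[1]):
            best = (score, length, mism, a_start, b_start, is_rc)
    if best is None:
        return None
    score, length, mism, a_start, b_start, is_rc = best
    identity = (length - mism) / length
    if identity >= min_identity and length >= min_len and mism <= max_mismatch:
        return HspResult(
            length=length, identity=identity, mismatches=mism,
            fc_offset=a_start, br_offset=b_start, br_revcomp=is_rc,
        )
    return None


def assemble(
    fc, br,
    min_overlap: int = 80,
    max_mismatch_frac: float = 0.02,
    specimen: str | None = None,
) -> AssembledBarcode | None:
    """Assemble one screened FC/BR pair through their terminal overlap.

    ``br`` must already be in the orientation chosen by the screen. Scans
    suffix(FC)/prefix(BR) overlaps longest-first and accepts the first whose
    mismatch fraction is <= ``max_mismatch_frac``; returns ``None``
    (unassembled) if no overlap of at least ``min_overlap`` nt qualifies.
    """
    fc_seq, br_seq = _centroid(fc), _centroid(br)
    fc_size = fc.size if isinstance(fc, Cluster) else 1
    br_size = br.size if isinstance(br, Cluster) else 1
    a = encode(fc_seq)
    b = encode(br_seq)
    na, nb = len(a), len(b)
    for olap in range(min(na, nb), min_overlap - 1, -1):
        mism_mask = a[na - olap:] != b[:olap]
        mism = int(np.count_nonzero(mism_mask))
        if mism > max_mismatch_frac * olap:
            continue
        # consensus: the larger cluster wins a disagreement, FC wins ties
        take_br = mism_mask & (br_size > fc_size)
        cons = np.where(take_br, b[:olap], a[na - olap:])
        seq = fc_seq[: na - olap] + cons.tobytes().decode("ascii") + br_seq[olap:]
        return AssembledBarcode(
            specimen=specimen, sequence=seq, overlap_length=olap,
            fc_size=fc_size, br_size=br_size,
        )
    return None


def pair_specimen(
    fc_clusters: list[Cluster],
    br_clusters: list[Cluster],
    min_identity: float = 0.98,
    min_len: int = 25,
    max_mismatch: int = 2,
    min_overlap: int = 80,
    max_mismatch_frac: float = 0.02,
    specimen: str | None = None,
) -> list[AssembledBarcode]:
    """Screen and assemble all FC x BR cluster pairs for one specimen.

    Every pair passing both the screen and the assembly becomes a candidate;
    candidates are then matched one-to-one greedily by descending support
    (min of the two cluster sizes; ties by FC size, then centroid order) so
    that each FC and each BR cluster appears in at most one barcode. Output
    is sorted by descending support.
    """
    candidates = []
    for i, fc in enumerate(fc_clusters):
        for j, br in enumerate(br_clusters):
            hsp = screen_pair(fc, br, min_identity, min_len, max_mismatch)
            if hsp is None:
                continue
            oriented = br if not hsp.br_revcomp else Cluster(
                centroid=revcomp(br.centroid), size=br.size, members=br.members)
            asm = assemble(fc, oriented, min_overlap, max_mismatch_frac, specimen)
            if asm is not None:
                candidates.append((i, j, asm))
    candidates.sort(key=lambda t: (
        -t[2].support, -t[2].fc_size, fc_clusters[t[0]].centroid, t[0], t[1]))
    used_fc: set[int] = set()
    used_br: set[int] = set()
    out = []
    for i, j, asm in candidates:
        if i in used_fc or j in used_br:
            continue
        used_fc.add(i)
        used_br.add(j)
        out.append(asm)
    out.sort(key=lambda a: -a.support)
    return out
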