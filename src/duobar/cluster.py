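"""Dereplication, de novo chimera removal, and greedy centroid clustering.

These operate per specimen x fragment on primer/MID-trimmed inserts.

Dereplication collapses exact full-length duplicates while retaining counts
(singletons included). Chimera detection is a de novo two-parent crossover
test in the UCHIME family: a query can only be explained as a chimera by
sequences sufficiently more abundant than itself (the putative parents,
which by PCR arithmetic must have been present earlier in the reaction).
Clustering is greedy centroid assignment in descending-abundance order: a
sequence joins the first centroid it matches at the identity threshold,
otherwise founds a new cluster — the classic UCLUST-style scheme, made
deterministic by ordering on (count desc, sequence lex).

Identity between two sequences is the fraction of identical columns of the
optimal global alignment (match +1, mismatch -1, gap open -2, gap extend
-1); see :func:`duobar._seq.alignment_identity`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from ._seq import alignment_identity, encode, global_alignment

__all__ = [
    "UniqueSeq", "Cluster", "dereplicate", "detect_chimeras", "greedy_cluster",
]


@dataclass
class UniqueSeq:
    """A dereplicated sequence with its read count."""

    sequence: str
    count: int
    specimen: str | None = None
    fragment: str | None = None


@dataclass
class Cluster:
    """A centroid with the members (and summed counts) it absorbed."""

    centroid: str
    size: int
    members: list[UniqueSeq] = field(default_factory=list)


def dereplicate(
    seqs: Iterable[str],
    specimen: str | None = None,
    fragment: str | None = None,
) -> list[UniqueSeq]:
    """Collapse exact duplicates, keeping counts; singletons are retained.

    Output is sorted by descending count, ties broken lexicographically —
    the canonical order every downstream step assumes.
    """
    counts = Counter(seqs)
    return [
        UniqueSeq(sequence=s, count=c, specimen=specimen, fragment=fragment)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def _match_profile(query: str, parent: str) -> np.ndarray:
    """Boolean per-query-position profile: does ``parent`` match ``query``?

    Equal-length inputs compare column-wise. Otherwise the parent is
    globally aligned to the query and projected onto query coordinates;
    query positions the parent fails to cover count as mismatches.
    """
    if len(parent) == len(query):
        return encode(query) == encode(parent)
    aln = global_alignment(query, parent)
    profile = np.zeros(len(query), dtype=bool)
    qidx = aln.indices[0]  # query position per column, -1 at query gaps
    qseq, pseq = aln[0], aln[1]
    for col, qpos in enumerate(qidx):
        if qpos >= 0 and qseq[col] == pseq[col] and qseq[col] != "-":
            profile[qpos] = True
    return profile


def detect_chimeras(
    uniques: Sequence[UniqueSeq],
    min_parent_fold: float = 2.0,
    min_div: float = 0.008,
    min_score: float = 0.28,
    max_parents: int = 16,
    beta: float = 8.0,
    abstain_weight: float = 0.5,
) -> set[str]:
    """Flag sequences explainable as two-parent PCR crossovers.

    For each query (in descending abundance), candidate parents are unflagged
    uniques with count >= ``min_parent_fold`` x the query's count. Over all
    parent pairs and crossover points, the best two-segment model is found;
    the query is flagged when (i) the model matches strictly more positions
    than the best single parent, (ii) the query diverges >= ``min_div`` from
    every candidate parent, and (iii) the vote score

        h = Y / (Y + beta*N + abstain_weight*A)

    reaches ``min_score``, where, over columns at which exactly at most one
    parent matches the query, Y counts columns supporting the model's local
    parent, N columns supporting the other parent, and A columns matching
    neither. ``beta`` weights contradicting votes heavily so that genuine
    biological variants straddling two references are not flagged.

    Returns the set of flagged sequences. With fewer than two candidate
    parents a query cannot be flagged.
    """
    order = sorted(uniques, key=lambda u: (-u.count, u.sequence))
    flagged: set[str] = set()
    # Descending abundance: once a sequence is flagged it can no longer
    # serve as a parent for the less abundant queries examined after it.
    for query in order:
        parents = [
            u for u in order
            if u.sequence not in flagged
            and u.sequence != query.sequence
            and u.count >= min_parent_fold * query.count
        ][:max_parents]
        if len(parents) < 2:
            continue
        L = len(query.sequence)
        profiles = {p.sequence: _match_profile(query.sequence, p.sequence)
                    for p in parents}
        # Closest-parent guard: a query nearly identical to one parent is a
        # (possibly erroneous) copy of it, not a chimera.
        max_single = max(int(prof.sum()) for prof in profiles.values())
        if (L - max_single) / L < min_div:
            continue
        is_chimera = False
        for pa, pb in combinations(parents, 2):
            ma, mb = profiles[pa.sequence], profiles[pb.sequence]
            ca = np.concatenate([[0], np.cumsum(ma)])
            cb = np.concatenate([[0], np.cumsum(mb)])
            tot_a, tot_b = int(ca[-1]), int(cb[-1])
            best_single = max(tot_a, tot_b)
            # model A[0:x) + B[x:L) and the reverse order
            ab = ca[:L + 1] + (tot_b - cb[:L + 1])
            ba = cb[:L + 1] + (tot_a - ca[:L + 1])
            x_ab = int(np.argmax(ab))
            x_ba = int(np.argmax(ba))
            if ab[x_ab] >= ba[x_ba]:
                model_matches, x, first, second = int(ab[x_ab]), x_ab, ma, mb
            else:
                model_matches, x, first, second = int(ba[x_ba]), x_ba, mb, ma
            if model_matches <= best_single:
                continue
            # votes over columns where the parents disagree about the query
            idx = np.arange(L)
            local = np.where(idx < x, first, second)
            other = np.where(idx < x, second, first)
            informative = local != other
            yes = int(np.count_nonzero(informative & local))
            no = int(np.count_nonzero(informative & other))
            abstain = int(np.count_nonzero(~local & ~other))
            denom = yes + beta * no + abstain_weight * abstain
            if denom == 0:
                continue
            if yes / denom >= min_score:
                is_chimera = True
                break
        if is_chimera:
            flagged.add(query.sequence)
    return flagged


def greedy_cluster(
    uniques: Sequence[UniqueSeq],
    identity: float = 0.99,
) -> list[Cluster]:
    """Greedy centroid clustering at the given identity threshold.

    Scans uniques in canonical order (descending count, lexicographic ties);
    each sequence joins the first existing centroid it matches at
    ``identity`` or better, else founds a new cluster. Cluster sizes are the
    summed member counts; the result is sorted by descending size (founding
    order breaks ties).
    """
    order = sorted(uniques, key=lambda u: (-u.count, u.sequence))
    clusters: list[Cluster] = []
    for u in order:
        for cl in clusters:
            if alignment_identity(cl.centroid, u.sequence) >= identity:
                cl.members.append(u)
                cl.size += u.count
                break
        else:
            clusters.append(Cluster(centroid=u.sequence, size=u.count, members=[u]))
    clusters.sort(key=lambda c: -c.size)
    return clusters
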