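"""Kimura 2-parameter distances, neighbor-joining trees, and concordance
between barcodes called from short-read data and Sanger references.

K2P separates transitions (A<->G, C<->T, fraction ``P`` of compared sites)
from transversions (fraction ``Q``):

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Sites where either sequence carries a gap, ``N`` or other ambiguity are
excluded pairwise (pairwise deletion). Saturated pairs (a non-positive log
argument) raise rather than returning infinity.

The neighbor-joining implementation is the standard Saitou-Nei algorithm
with the Q-criterion, joining the lowest-index pair on ties so that results
are reproducible. Trees are returned as Newick strings with branch lengths
as computed (NJ branch lengths can legitimately be negative and are not
clamped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import global_alignment
from .calling import BarcodeRecord

__all__ = [
    "DistanceMatrix", "k2p", "p_distance", "k2p_matrix", "nj",
    "sanger_concordance", "SaturationError",
]

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_VALID = {"A", "C", "G", "T"}


class SaturationError(ValueError):
    """Raised when substitution saturation makes the K2P distance undefined."""


def _pair_sites(a: str, b: str, aligned: bool):
    """Yield comparable site pairs after pairwise deletion.

    Unequal-length inputs are globally aligned first unless ``aligned`` is
    set, in which case a length mismatch is an error.
    """
    if len(a) != len(b):
        if aligned:
            raise ValueError("aligned sequences must have equal length")
        aln = global_alignment(a, b)
        a, b = str(aln[0]), str(aln[1])
    for x, y in zip(a.upper(), b.upper()):
        if x in _VALID and y in _VALID:
            yield x, y


def _pq(a: str, b: str, aligned: bool = True) -> tuple[float, float, int]:
    sites = transitions = transversions = 0
    for x, y in _pair_sites(a, b, aligned):
        sites += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    return transitions / sites, transversions / sites, sites


def k2p(a: str, b: str, aligned: bool = True) -> float:
    """Kimura 2-parameter distance in substitutions per site."""
    P, Q, _ = _pq(a, b, aligned)
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"substitution saturation (P={P:.3f}, Q={Q:.3f}): K2P undefined")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def p_distance(a: str, b: str, aligned: bool = True) -> float:
    """Proportion of differing sites, with pairwise deletion."""
    P, Q, _ = _pq(a, b, aligned)
    return P + Q


@dataclass
class DistanceMatrix:
    """A labelled symmetric distance matrix with a PHYLIP square dialect."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.d):
                fields = " ".join(f"{x:.10f}" for x in row)
                fh.write(f"{label}  {fields}\n")

    @classmethod
    def from_phylip(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            labels, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(labels=labels, d=np.array(rows))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)


def k2p_matrix(named_seqs: Sequence[tuple[str, str]], aligned: bool = True) -> DistanceMatrix:
    """All-pairs K2P distance matrix for labelled sequences."""
    labels = [name for name, _ in named_seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate labels")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = k2p(named_seqs[i][1], named_seqs[j][1], aligned)
    return DistanceMatrix(labels=labels, d=d)


def nj(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted Newick string.

    Ties in the Q-criterion are resolved toward the lowest index pair.
    Requires at least three taxa.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.d.astype(float).copy()
    nodes = [f"{_escape(label)}" for label in dm.labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair on ties: scan the upper triangle in order
        iu, ju = np.triu_indices(m, k=1)
        k = int(np.argmin(q[iu, ju]))
        i, j = int(iu[k]), int(ju[k])
        dij = sub[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        gi, gj = active[i], active[j]
        new_newick = f"({nodes[gi]}:{vi:.10g},{nodes[gj]}:{vj:.10g})"
        # distances from the new node u to every other active node
        d_new = 0.5 * (d[gi, :] + d[gj, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = d_new
        d[:-1, -1] = d_new
        d[-1, -1] = 0.0
        nodes.append(new_newick)
        gu = d.shape[0] - 1
        active = [g for g in active if g not in (gi, gj)] + [gu]

    ga, gb, gc = active
    dab, dac, dbc = d[ga, gb], d[ga, gc], d[gb, gc]
    va = 0.5 * (dab + dac - dbc)
    vb = 0.5 * (dab + dbc - dac)
    vc = 0.5 * (dac + dbc - dab)
    return (f"({nodes[ga]}:{va:.10g},{nodes[gb]}:{vb:.10g},"
            f"{nodes[gc]}:{vc:.10g});")


def _escape(label: str) -> str:
    if any(c in label for c in " ,();:'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def sanger_concordance(
    calls: Sequence[BarcodeRecord],
    sanger: Mapping[str, str],
    threshold: float = 0.02,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pairwise distances between each specimen's called sequences and its
    Sanger reference.

    Per specimen, every reported sequence is compared to the Sanger sequence
    (p-distance and K2P over a pairwise alignment when lengths differ) and
    ranked by similarity; a pair is concordant when its p-distance is
    strictly below ``threshold`` (default 2%). The summary counts specimens
    whose best pair is concordant, plus specimens excluded for lacking a
    Sanger or a called sequence.
    """
    rows = []
    no_sanger = hts_none = 0
    for rec in calls:
        if rec.specimen not in sanger:
            no_sanger += 1
            continue
        if not rec.sequences:
            hts_none += 1
            continue
        ref = sanger[rec.specimen].upper()
        dists = []
        for cs in rec.sequences:
            pd_ = p_distance(cs.sequence, ref, aligned=(len(cs.sequence) == len(ref)))
            try:
                kd = k2p(cs.sequence, ref, aligned=(len(cs.sequence) == len(ref)))
            except SaturationError:
                kd = float("nan")
            dists.append((pd_, kd, cs))
        dists.sort(key=lambda t: t[0])
        for rank, (pd_, kd, cs) in enumerate(dists, start=1):
            rows.append({
                "specimen": rec.specimen, "rank": rank, "p_distance": pd_,
                "k2p": kd, "abundance_fraction": cs.abundance_fraction,
                "concordant": pd_ < threshold,
            })
    df = pd.DataFrame(rows, columns=[
        "specimen", "rank", "p_distance", "k2p", "abundance_fraction",
        "concordant"])
    best = df[df["rank"] == 1]
    summary = {
        "compared": int(len(best)),
        "concordant": int(best["concordant"].sum()),
        "discordant": int((~best["concordant"]).sum()),
        "no_sanger": no_sanger,
        "hts_none": hts_none,
    }
    return df, summary
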