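"""Dereplication, chimera detection, and greedy centroid clustering."""

import numpy as np
import pytest
from Bio import Align

from duobar.cluster import (
    UniqueSeq, dereplicate, detect_chimeras, greedy_cluster,
)

from conftest import random_seq


class TestDereplicate:
    def test_counts_and_canonical_order(self):
        out = dereplicate(["ACGT", "ACGT", "ACGT", "TTTT"])
        assert [(u.sequence, u.count) for u in out] == [("ACGT", 3), ("TTTT", 1)]

    def test_all_distinct_and_all_identical(self):
        distinct = dereplicate(["AA", "CC", "GG"])
        assert all(u.count == 1 for u in distinct)
        assert [u.sequence for u in distinct] == ["AA", "CC", "GG"]  # lexicographic
        (one,) = dereplicate(["ACGT"] * 1000)
        assert one.count == 1000

    def test_conservation(self):
        seqs = ["A", "C", "A", "G", "A", "C"]
        assert sum(u.count for u in dereplicate(seqs)) == len(seqs)


def _mutate(seq, positions, rng):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestDetectChimeras:
    def _parents(self, seed=20, length=300, div=0.05):
        rng = np.random.default_rng(seed)
        a = random_seq(rng, length)
        positions = rng.choice(length, size=int(div * length), replace=False)
        b = _mutate(a, positions, rng)
        return a, b

    def test_constructed_crossovers_are_flagged(self):
        """A two-parent crossover at any middle-third breakpoint is flagged
        when both parents are abundant."""
        a, b = self._parents()
        for k in range(100, 201, 20):
            query = a[:k] + b[k:]
            uniques = [UniqueSeq(a, 100), UniqueSeq(b, 100), UniqueSeq(query, 1)]
            assert detect_chimeras(uniques) == {query}, f"breakpoint {k}"

    def test_parent_copy_not_flagged(self):
        a, b = self._parents(21)
        uniques = [UniqueSeq(a, 100), UniqueSeq(b, 100), UniqueSeq(a, 1)]
        # dereplication would normally collapse these; even so, zero
        # divergence from a single parent must never be called chimeric
        assert detect_chimeras(uniques) == set()

    def test_sequencing_error_copies_not_flagged(self):
        a, b = self._parents(22)
        rng = np.random.default_rng(22)
        noisy = _mutate(a, rng.choice(300, size=2, replace=False), rng)
        uniques = [UniqueSeq(a, 100), UniqueSeq(b, 40), UniqueSeq(noisy, 1)]
        assert detect_chimeras(uniques) == set()

    def test_single_unique_cannot_be_flagged(self):
        assert detect_chimeras([UniqueSeq("ACGT" * 50, 5)]) == set()

    def test_needs_two_abundant_parents(self):
        a, b = self._parents(23)
        query = a[:150] + b[150:]
        # parent B is not >= 2x the query's count -> only one candidate parent
        uniques = [UniqueSeq(a, 100), UniqueSeq(b, 5), UniqueSeq(query, 4)]
        assert detect_chimeras(uniques) == set()

    def test_clean_simulator_run_flags_nothing(self, clean_sim):
        """Zero chimera rate + zero error: no specimen has a flagged read."""
        from duobar.calling import ReferenceDb
        from duobar.pipeline import PipelineConfig, run_all

        res = run_all(clean_sim.reads, clean_sim.mapping, clean_sim.primers,
                      PipelineConfig())
        assert all(not flagged for flagged in res.chimeras.values())

    def test_simulator_chimera_recovery(self, noisy_sim, noisy_result):
        """Simulator-labelled chimeras whose parents are abundant (>=10x)
        are flagged at >=90% sensitivity with no true barcode flagged."""
        truth = noisy_sim.truth
        by_read = {r.read_id: r for r in noisy_result.demux_records}
        origin_counts = {}
        for r in noisy_result.demux_records:
            key = (r.specimen, r.fragment)
            o = truth.read_origins[r.read_id]
            origin_counts.setdefault(key, {}).setdefault(o, 0)
            origin_counts[key][o] += 1
        eligible = flagged = 0
        for rid, origin in truth.read_origins.items():
            if origin != "chimera" or rid not in by_read:
                continue
            rec = by_read[rid]
            key = (rec.specimen, rec.fragment)
            pa, pb = truth.chimera_parents[rid]
            counts = origin_counts[key]
            if min(counts.get(pa, 0), counts.get(pb, 0)) < 10:
                continue
            eligible += 1
            if rec.insert in noisy_result.chimeras[key]:
                flagged += 1
        assert eligible >= 10  # the fixture must actually exercise the test
        assert flagged / eligible >= 0.90
        # no specimen's true fragment sequence is ever flagged
        for (specimen, fragment), flags in noisy_result.chimeras.items():
            lo, hi = noisy_sim.config.span_for(fragment)
            assert truth.specimens[specimen].barcode[lo:hi] not in flags


def _oracle_identity(a, b):
    """Alignment identity computed directly with Biopython, independently of
    the package's helper."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(s1, s2))
    return matches / len(s1)


def _oracle_greedy(uniques, identity):
    """Literal replay of the greedy definition: scan in canonical order,
    join the first centroid within threshold, else found a new cluster."""
    order = sorted(uniques, key=lambda u: (-u.count, u.sequence))
    clusters = []  # (centroid, [members])
    for u in order:
        for c in clusters:
            if _oracle_identity(c[0], u.sequence) >= identity:
                c[1].append(u)
                break
        else:
            clusters.append((u.sequence, [u]))
    return sorted(
        [(c[0], sum(m.count for m in c[1])) for c in clusters],
        key=lambda t: -t[1])


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        out = greedy_cluster([UniqueSeq("ACGTACGT", 2), UniqueSeq("ACGTACGT", 1)])
        assert len(out) == 1 and out[0].size == 3

    def test_99_percent_boundary(self):
        """10 substitutions in 1000 nt (99.0%) co-cluster at the 0.99 cutoff;
        11 (98.9%) do not."""
        rng = np.random.default_rng(30)
        base = random_seq(rng, 1000)
        for n_mut, n_clusters in ((10, 1), (11, 2)):
            positions = rng.choice(1000, size=n_mut, replace=False)
            variant = _mutate(base, positions, rng)
            out = greedy_cluster([UniqueSeq(base, 5), UniqueSeq(variant, 1)])
            assert len(out) == n_clusters

    def test_most_abundant_is_centroid_and_sizes_sum(self):
        rng = np.random.default_rng(31)
        base = random_seq(rng, 500)
        v1 = _mutate(base, [10], rng)
        v2 = _mutate(base, [20, 30], rng)
        out = greedy_cluster([UniqueSeq(v1, 3), UniqueSeq(base, 5), UniqueSeq(v2, 1)])
        assert len(out) == 1
        assert out[0].centroid == base
        assert out[0].size == 9

    def test_conservation(self, noisy_sim, noisy_result):
        """Cluster sizes sum to the dereplicated, chimera-filtered read count
        for every specimen x fragment."""
        from duobar.cluster import dereplicate as derep

        grouped = {}
        for r in noisy_result.demux_records:
            grouped.setdefault((r.specimen, r.fragment), []).append(r.insert)
        for key, inserts in grouped.items():
            flagged = noisy_result.chimeras[key]
            kept = [s for s in inserts if s not in flagged]
            assert sum(c.size for c in noisy_result.clusters[key]) == len(kept)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_oracle(self, seed):
        """For small inputs, clustering equals a literal brute-force replay
        of the greedy definition built on an independent identity routine."""
        rng = np.random.default_rng(100 + seed)
        base = random_seq(rng, 120)
        uniques = []
        for i in range(int(rng.integers(2, 9))):
            n_mut = int(rng.integers(0, 6))
            positions = rng.choice(120, size=n_mut, replace=False)
            seq = _mutate(base, positions, rng) if n_mut else base
            uniques.append(UniqueSeq(seq, int(rng.integers(1, 50))))
        uniques = dereplicate(
            [u.sequence for u in uniques for _ in range(u.count)])
        got = [(c.centroid, c.size) for c in greedy_cluster(uniques, 0.97)]
        assert got == _oracle_greedy(uniques, 0.97)
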