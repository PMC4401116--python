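"""K2P distances, neighbor joining, and Sanger/HTS concordance."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from duobar.calling import BarcodeRecord, CalledSequence
from duobar.distances import (
    DistanceMatrix, SaturationError, k2p, k2p_matrix, nj, p_distance,
    sanger_concordance,
)

from conftest import random_seq


class TestK2P:
    def test_identical_sequences_zero(self):
        assert k2p("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_ten_transitions(self):
        """100 sites with 10 transitions, 0 transversions:
        d = -1/2 ln((1-2*0.1)*sqrt(1)) = -1/2 ln(0.8)."""
        a = "A" * 100
        b = "G" * 10 + "A" * 90  # A->G is a transition
        assert k2p(a, b) == pytest.approx(-0.5 * math.log(0.8), abs=1e-12)

    def test_transversions_enter_via_q(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90  # A->C transversion: P=0, Q=0.1
        expected = -0.5 * math.log((1 - 0.1) * math.sqrt(1 - 0.2))
        assert k2p(a, b) == pytest.approx(expected, abs=1e-12)

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            k2p("AAAA", "GGGG")

    def test_pairwise_deletion_of_ambiguous_sites(self):
        # the N/gap-free columns are identical -> distance 0
        assert k2p("ACGTN", "ACGTA") == 0.0
        assert p_distance("ACNTA", "ACGTA") == 0.0

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_nonnegative_and_zero_iff_identical(self, seed):
        rng = np.random.default_rng(seed)
        a = random_seq(rng, 200)
        n_mut = int(rng.integers(0, 20))
        b = list(a)
        for p in rng.choice(200, size=n_mut, replace=False):
            b[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[p]]
        b = "".join(b)
        d = k2p(a, b)
        assert d >= 0.0
        assert (d == 0.0) == (a == b)


def _random_additive_tree(rng, n_leaves):
    """Random binary tree with positive branch lengths; returns the leaf
    distance matrix computed independently of any NJ code."""
    nodes = {i: None for i in range(n_leaves)}  # leaf id -> parent link later
    # leaf-to-leaf distances via path sums on an explicit tree structure
    children = {}
    lengths = {}
    next_id = n_leaves
    active = list(range(n_leaves))
    while len(active) > 1:
        i = active.pop(int(rng.integers(len(active))))
        j = active.pop(int(rng.integers(len(active))))
        parent = next_id
        next_id += 1
        children[parent] = (i, j)
        lengths[i] = float(rng.uniform(0.05, 1.0))
        lengths[j] = float(rng.uniform(0.05, 1.0))
        active.append(parent)
    root = active[0]

    # distances from every node down to its descendant leaves
    def leaf_dists(node):
        if node < n_leaves:
            return {node: 0.0}
        out = {}
        for child in children[node]:
            for leaf, d in leaf_dists(child).items():
                out[leaf] = d + lengths[child]
        return out

    d = np.zeros((n_leaves, n_leaves))

    def fill(node):
        if node < n_leaves:
            return
        a, b = children[node]
        da, db = leaf_dists(a), leaf_dists(b)
        for la, va in da.items():
            for lb, vb in db.items():
                dist = va + lengths[a] + vb + lengths[b]
                d[la, lb] = d[lb, la] = dist
        fill(a)
        fill(b)

    fill(root)
    return d


def _tree_distances(newick, labels):
    """Leaf-to-leaf path lengths of a Newick tree, via scikit-bio."""
    from skbio import TreeNode

    tree = TreeNode.read(io.StringIO(newick))
    tips = {t.name: t for t in tree.tips()}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = tips[labels[i]].distance(tips[labels[j]])
    return out


class TestNJ:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(labels=["a", "b", "c"],
                            d=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        newick = nj(dm)
        got = _tree_distances(newick, ["a", "b", "c"])
        assert np.allclose(got, dm.d, atol=1e-9)
        # v_a = (d_ab + d_ac - d_bc)/2 = 1
        from skbio import TreeNode
        tree = TreeNode.read(io.StringIO(newick))
        assert {t.name: t.length for t in tree.tips()} == \
               pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_fewer_than_three_taxa_is_error(self):
        dm = DistanceMatrix(labels=["a", "b"], d=np.array([[0, 1], [1, 0.]]))
        with pytest.raises(ValueError):
            nj(dm)

    @pytest.mark.parametrize("seed,n_leaves", [(0, 4), (1, 6), (2, 8), (3, 10)])
    def test_additive_matrices_recovered_exactly(self, seed, n_leaves):
        """NJ is exact on additive distances: the output tree's path-length
        matrix reproduces the input to 1e-9."""
        rng = np.random.default_rng(300 + seed)
        d = _random_additive_tree(rng, n_leaves)
        labels = [f"t{i}" for i in range(n_leaves)]
        newick = nj(DistanceMatrix(labels=labels, d=d))
        got = _tree_distances(newick, labels)
        assert np.allclose(got, d, atol=1e-9)

    def test_topology_agrees_with_independent_implementation(self):
        """On a generic random matrix our NJ and scikit-bio's NJ produce the
        same unrooted topology."""
        import skbio

        rng = np.random.default_rng(310)
        n = 7
        base = rng.uniform(0.2, 1.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        labels = [f"t{i}" for i in range(n)]
        ours = skbio.TreeNode.read(io.StringIO(nj(DistanceMatrix(labels, d))))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        rf = ours.compare_rfd(theirs)
        assert rf == 0.0

    def test_ultrametric_tie_joins_lowest_index_pair(self):
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        newick = nj(DistanceMatrix(labels=["a", "b", "c", "d"], d=d))
        # the first join must be (a, b): they form the inner clade
        assert "(a:1,b:1)" in newick


class TestPhylipRoundtrip:
    def test_matrix_roundtrips(self, tmp_path):
        rng = np.random.default_rng(320)
        base = random_seq(rng, 300)
        seqs = [("s0", base)]
        for i in range(1, 5):
            mutant = list(base)
            for p in rng.choice(300, size=10 * i, replace=False):
                mutant[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutant[p]]
            seqs.append((f"s{i}", "".join(mutant)))
        dm = k2p_matrix(seqs)
        p = tmp_path / "dist.phy"
        dm.to_phylip(p)
        back = DistanceMatrix.from_phylip(p)
        assert back.labels == dm.labels
        assert np.allclose(back.d, dm.d, atol=1e-9)


class TestSangerConcordance:
    def _record(self, specimen, seq):
        return BarcodeRecord(specimen=specimen, status="single",
                             sequences=[CalledSequence(seq, 1.0)])

    def test_identical_pair_concordant(self):
        rng = np.random.default_rng(330)
        s = random_seq(rng, 658)
        df, summary = sanger_concordance([self._record("S1", s)], {"S1": s})
        assert df.iloc[0]["p_distance"] == 0.0
        assert bool(df.iloc[0]["concordant"])
        assert summary["concordant"] == 1

    @pytest.mark.parametrize("n_diff,concordant", [(13, True), (14, False)])
    def test_two_percent_boundary_on_658nt(self, n_diff, concordant):
        """13/658 = 1.98% is under the 2% threshold; 14/658 = 2.13% is not."""
        rng = np.random.default_rng(331)
        s = random_seq(rng, 658)
        other = list(s)
        for p in rng.choice(658, size=n_diff, replace=False):
            other[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[p]]
        df, summary = sanger_concordance(
            [self._record("S1", "".join(other))], {"S1": s})
        assert bool(df.iloc[0]["concordant"]) is concordant

    def test_missing_inputs_tallied(self):
        records = [
            self._record("S1", "ACGT" * 100),
            BarcodeRecord(specimen="S2", status="none", sequences=[]),
            self._record("S3", "ACGT" * 100),
        ]
        sanger = {"S1": "ACGT" * 100, "S2": "ACGT" * 100}
        _, summary = sanger_concordance(records, sanger)
        assert summary["compared"] == 1
        assert summary["hts_none"] == 1
        assert summary["no_sanger"] == 1
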