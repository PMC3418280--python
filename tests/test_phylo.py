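import dendropy
import numpy as np
import pytest

from _oracles import (
    all_topologies,
    path_length_matrix,
    random_additive_tree,
    tree_bipartitions,
)
from spongedelim.distmat import DistanceMatrix, distance_matrix
from spongedelim.phylo import (
    PhyloError,
    bipartitions,
    bootstrap_support,
    branch_and_bound_mp,
    fitch_length,
    is_monophyletic,
    nj,
    read_newick,
    write_newick,
)
from spongedelim.seqio import MultipleAlignment


def aln(ids, seqs):
    return MultipleAlignment("L", list(ids), list(seqs))


def edge_lengths(tree):
    out = {}
    for leaf in tree.leaf_node_iter():
        out[leaf.taxon.label] = leaf.edge.length
    return out


class TestNJ:
    def test_additive_four_taxon_oracle(self):
        # additive matrix solved by hand: split AB|CD, internal edge 1,
        # leaf edges A=1 B=2 C=3 D=4 (four-point condition checked offline)
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        tree = nj(DistanceMatrix(labels, d))
        assert bipartitions(tree) == {frozenset({"C", "D"})}
        lengths = edge_lengths(tree)
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})
        # internal edge length 1
        internal = [
            e.length
            for e in tree.preorder_edge_iter()
            if e.head_node and not e.head_node.is_leaf() and e.tail_node
        ]
        assert internal == pytest.approx([1.0])

    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], dtype=float)
        tree = nj(DistanceMatrix(labels, d))
        lengths = edge_lengths(tree)
        # vA = (dAB + dAC - dBC)/2 = 0, vB = 2, vC = 3
        assert lengths == pytest.approx({"A": 0.0, "B": 2.0, "C": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(PhyloError):
            nj(DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_agrees_with_skbio_on_random_matrices(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        for _ in range(10):
            adj, leaves, true_bips = random_additive_tree(
                rng, int(rng.integers(5, 8))
            )
            d = path_length_matrix(adj, leaves)
            ours = bipartitions(nj(DistanceMatrix(leaves, d)))
            sk_tree = skbio_nj(skbio.DistanceMatrix(d, leaves))
            theirs = set()
            ref = min(leaves)
            n = len(leaves)
            for node in sk_tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                side = side if ref not in side else frozenset(set(leaves) - side)
                if 2 <= len(side) <= n - 2:
                    theirs.add(side)
            assert ours == theirs == true_bips

    def test_negative_branch_estimates_clamped(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(4, 7))
            d = rng.uniform(0.0, 1.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = nj(DistanceMatrix([f"t{i}" for i in range(n)], d))
            for e in tree.preorder_edge_iter():
                if e.length is not None:
                    assert e.length >= 0


class TestMonophyly:
    def test_explicit_bipartition(self):
        t = read_newick("((A,B),(C,D));")
        assert is_monophyletic(t, {"A", "B"})

    def test_crossing_split(self):
        t = read_newick("((A,B),(C,D));")
        assert not is_monophyletic(t, {"A", "C"})

    def test_singleton_and_complement(self):
        t = read_newick("((A,B),(C,D));")
        assert is_monophyletic(t, {"A"})
        assert is_monophyletic(t, {"B", "C", "D"})

    def test_unknown_label(self):
        t = read_newick("((A,B),(C,D));")
        with pytest.raises(PhyloError, match="unknown"):
            is_monophyletic(t, {"A", "Z"})


class TestNewick:
    def test_round_trip_topology_lengths_supports(self):
        text = "(A:1.5,'B c':2.25,(C:1.0,D_x:1.0)91:0.5);"
        tree = read_newick(text)
        again = read_newick(write_newick(tree))
        assert bipartitions(again) == bipartitions(tree)
        assert edge_lengths(again) == edge_lengths(tree)
        assert "91" in write_newick(again)

    def test_unrooted_quartet_parse(self):
        tree = read_newick("(A,B,(C,D));")
        assert bipartitions(tree) == {frozenset({"C", "D"})}

    def test_malformed_newick(self):
        with pytest.raises(PhyloError, match="malformed"):
            read_newick("((A,B);")


class TestFitch:
    def test_single_synapomorphy(self):
        a = aln("ABCD", ["A", "A", "G", "G"])
        assert fitch_length(a, read_newick("((A,B),(C,D));")) == 1

    def test_forced_homoplasy(self):
        a = aln("ABCD", ["A", "A", "G", "G"])
        assert fitch_length(a, read_newick("((A,C),(B,D));")) == 2

    def test_invariant_alignment_zero(self):
        a = aln("ABCD", ["ACG", "ACG", "ACG", "ACG"])
        assert fitch_length(a, read_newick("((A,B),(C,D));")) == 0

    def test_missing_data_contributes_no_cost(self):
        a = aln("ABCD", ["A-", "AN", "GA", "GA"])
        assert fitch_length(a, read_newick("((A,B),(C,D));")) == 1

    def test_invariant_under_rerooting_and_leaf_order(self):
        rng = np.random.default_rng(8)
        a = aln(
            "ABCDE",
            ["".join(rng.choice(list("ACGT"), 12)) for _ in range(5)],
        )
        forms = [
            "((A,B),(C,D),E);",
            "(E,(C,D),(B,A));",
            "((C,D),((A,B),E));",
        ]
        lengths = {fitch_length(a, read_newick(f)) for f in forms}
        assert len(lengths) == 1

    def test_agrees_with_dendropy_fitch(self):
        from dendropy.model.parsimony import fitch_down_pass

        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(4, 7))
            ids = [f"t{i}" for i in range(n)]
            a = aln(ids, ["".join(rng.choice(list("ACGT"), 15)) for _ in range(n)])
            length, trees = branch_and_bound_mp(a)
            tree = trees[0]
            taxa = tree.taxon_namespace
            data = dendropy.DnaCharacterMatrix.get(
                data="".join(f">{i}\n{a.row(i)}\n" for i in ids),
                schema="fasta",
                taxon_namespace=taxa,
            )
            sets = data.taxon_state_sets_map(gaps_as_missing=True)
            score = fitch_down_pass(tree.postorder_node_iter(), taxon_state_sets_map=sets)
            assert fitch_length(a, tree) == score == length

    def test_label_mismatch_rejected(self):
        a = aln("ABCD", ["A", "A", "G", "G"])
        with pytest.raises(PhyloError):
            fitch_length(a, read_newick("((A,B),(C,E));"))


class TestBranchAndBound:
    def test_matches_exhaustive_on_five_taxa(self):
        rng = np.random.default_rng(10)
        ids = [f"t{i}" for i in range(5)]
        a = aln(ids, ["".join(rng.choice(list("ACGT"), 10)) for _ in range(5)])
        best, trees = branch_and_bound_mp(a)
        scored = [
            (fitch_length(a, read_newick(nwk)), nwk)
            for nwk in all_topologies(ids)
        ]
        true_best = min(s for s, _ in scored)
        optimal = {
            frozenset(bipartitions(read_newick(nwk)))
            for s, nwk in scored
            if s == true_best
        }
        assert best == true_best
        assert {frozenset(bipartitions(t)) for t in trees} == optimal

    def test_no_signal_returns_all_topologies(self):
        a = aln("ABCDE", ["ACGT"] * 5)
        best, trees = branch_and_bound_mp(a)
        assert best == 0
        assert len(trees) == 15  # all unrooted binary topologies on 5 taxa

    def test_guard_rail(self):
        ids = [f"t{i}" for i in range(16)]
        a = aln(ids, ["ACGT"] * 16)
        with pytest.raises(PhyloError, match="guard"):
            branch_and_bound_mp(a)


class TestBootstrap:
    def test_unanimous_columns_give_support_100(self):
        a = aln("ABCD", ["AAAA", "AAAA", "GGGG", "GGGG"])
        result = bootstrap_support(a, n_reps=50, seed=0)
        assert result.supports[frozenset({"C", "D"})] == 100.0

    def test_same_seed_same_supports(self, mimic_truth):
        its = mimic_truth.alignments["ITS"]
        r1 = bootstrap_support(its, 30, seed=42)
        r2 = bootstrap_support(its, 30, seed=42)
        assert r1.supports == r2.supports

    def test_planted_synapomorphies_strongly_supported(self):
        # 6 taxa, three 2-taxon clades with 50 clean synapomorphies each
        ids = list("ABCDEF")
        blocks = {
            frozenset("AB"): "T",
            frozenset("CD"): "G",
            frozenset("EF"): "C",
        }
        cols = []
        for clade, state in blocks.items():
            for _ in range(50):
                cols.append(["".join(state if i in clade else "A") for i in ids])
        cols += [["A"] * 6 for _ in range(50)]
        seqs = ["".join(col[k] for col in cols) for k in range(6)]
        result = bootstrap_support(aln(ids, seqs), n_reps=500, seed=1)
        ref = min(ids)
        for clade in blocks:
            side = (
                frozenset(clade)
                if ref not in clade
                else frozenset(set(ids) - clade)
            )
            assert result.supports.get(side, 0.0) >= 95.0

    def test_supports_in_range(self, mimic_truth):
        its = mimic_truth.alignments["ITS"]
        r = bootstrap_support(its, 25, seed=3)
        assert all(0.0 <= v <= 100.0 for v in r.supports.values())
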