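import itertools

import numpy as np
import pytest

from parvapop.errors import InputError, ParameterError
from parvapop.network import (
    PhyloTree,
    SiteWeightScheme,
    bootstrap_support,
    build_mj_network,
    nj_tree,
    weighted_distance,
)
from parvapop.popio import AlignedSequenceSet, table_from_records

UNIFORM = SiteWeightScheme(tv_multiplier=1.0)


def edge_seq_set(net):
    return {
        frozenset((net.graph.nodes[u]["sequence"], net.graph.nodes[v]["sequence"]))
        for u, v in net.graph.edges()
    }


class TestWeights:
    def test_transition_weight(self):
        assert weighted_distance("AAA", "GAA", SiteWeightScheme()) == 50.0

    def test_transversion_triple_weight(self):
        assert weighted_distance("AAA", "TAA", SiteWeightScheme()) == 150.0

    def test_homoplastic_site_downweighted(self):
        scheme = SiteWeightScheme(homoplastic_sites=frozenset({1}))
        assert weighted_distance("AAA", "GAA", scheme) == 1.0

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ParameterError):
            SiteWeightScheme(default_weight=0)


class TestMedianJoining:
    def test_two_haplotypes_single_edge(self):
        t = table_from_records(["a", "b"], ["AAA", "GAA"], ["P", "P"])
        net = build_mj_network(t, SiteWeightScheme())
        assert net.graph.number_of_edges() == 1
        (u, v, data), = net.graph.edges(data=True)
        assert data["weight"] == 50.0
        assert data["sites"] == (1,)

    def test_three_haplotype_star_no_median(self):
        t = table_from_records(["a", "b", "c"], ["AAA", "TAA", "ATA"], ["P"] * 3)
        net = build_mj_network(t, UNIFORM)
        assert net.median_vectors == []
        assert edge_seq_set(net) == {
            frozenset({"AAA", "TAA"}),
            frozenset({"AAA", "ATA"}),
        }

    def test_triplet_quasi_median_created(self):
        # 000 / 110 / 011 on a binary-encoded site triplet -> median 010
        t = table_from_records(["a", "b", "c"], ["AAA", "GGA", "AGG"], ["P"] * 3)
        net = build_mj_network(t, UNIFORM)
        assert net.median_vectors == ["AGA"]
        mv = [n for n, d in net.graph.nodes(data=True) if not d["sampled"]]
        assert len(mv) == 1 and net.graph.degree(mv[0]) == 3

    def test_all_sampled_haplotypes_present_and_connected(self, long_distance_hap):
        import networkx as nx

        net = build_mj_network(long_distance_hap, SiteWeightScheme())
        sampled = [n for n, d in net.graph.nodes(data=True) if d["sampled"]]
        assert set(sampled) == set(long_distance_hap.hap_ids)
        assert nx.is_connected(net.graph)
        for n, d in net.graph.nodes(data=True):
            if not d["sampled"]:
                assert net.graph.degree(n) >= 3

    def test_input_order_invariance(self, rng):
        seqs = ["AAAA", "GAAA", "GGAA", "GGGA", "AAGA", "AATA"]
        t1 = table_from_records([f"s{i}" for i in range(6)], seqs, ["P"] * 6)
        order = rng.permutation(6)
        t2 = table_from_records(
            [f"s{i}" for i in order], [seqs[i] for i in order], ["P"] * 6
        )
        n1 = build_mj_network(t1, UNIFORM)
        n2 = build_mj_network(t2, UNIFORM)
        assert edge_seq_set(n1) == edge_seq_set(n2)

    def test_exclusions_respected(self):
        t = table_from_records(["a", "b", "c"], ["AAA", "GAA", "GGA"], ["P"] * 3)
        net = build_mj_network(t, SiteWeightScheme(), exclusions={"H3"})
        assert set(net.sampled) == {"H1", "H2"}


def random_additive_tree(n_taxa, rng):
    """Random unrooted binary tree with exponential branch lengths; returns
    (leaf labels, pairwise distance matrix)."""
    import networkx as nx

    g = nx.Graph()
    leaves = [f"L{i}" for i in range(n_taxa)]
    g.add_edge(leaves[0], leaves[1], length=float(rng.exponential(1.0) + 0.05))
    inner = 0
    for leaf in leaves[2:]:
        u, v = list(g.edges())[rng.integers(g.number_of_edges())]
        w = g.edges[u, v]["length"]
        inner += 1
        mid = f"X{inner}"
        g.remove_edge(u, v)
        split = rng.uniform(0.1, 0.9) * w
        g.add_edge(u, mid, length=split)
        g.add_edge(mid, v, length=w - split)
        g.add_edge(mid, leaf, length=float(rng.exponential(1.0) + 0.05))
    D = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        D[i, j] = D[j, i] = nx.shortest_path_length(g, leaves[i], leaves[j], weight="length")
    return leaves, D


class TestNeighbourJoining:
    def test_three_taxa_exact_lengths(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = nj_tree(D, ["a", "b", "c"])
        assert tree.leaf_distance("a", "b") == pytest.approx(5)
        assert tree.leaf_distance("a", "c") == pytest.approx(9)
        assert tree.leaf_distance("b", "c") == pytest.approx(10)

    def test_four_taxon_additive_matrix_recovered(self):
        # tree ((A:1,B:2),(C:3,D:4)) with internal branch 1
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = nj_tree(D, ["A", "B", "C", "D"])
        for (i, a), (j, b) in itertools.combinations(enumerate("ABCD"), 2):
            assert tree.leaf_distance(a, b) == pytest.approx(D[i, j])

    def test_taxon_order_invariance(self, rng):
        leaves, D = random_additive_tree(6, rng)
        t1 = nj_tree(D, leaves)
        order = rng.permutation(6)
        t2 = nj_tree(D[np.ix_(order, order)], [leaves[i] for i in order])
        assert set(t1.bipartitions()) == set(t2.bipartitions())

    def test_nan_rejected(self):
        D = np.array([[0, 1, np.nan], [1, 0, 1], [np.nan, 1, 0]])
        with pytest.raises(InputError):
            nj_tree(D, ["a", "b", "c"])

    def test_newick_is_parseable(self):
        from io import StringIO

        from Bio import Phylo

        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float)
        tree = nj_tree(D, ["A", "B", "C", "D"])
        parsed = Phylo.read(StringIO(tree.newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == ["A", "B", "C", "D"]


class TestBootstrap:
    def _clade_alignment(self):
        # two clearly separated 3-leaf clades: 10 diagnostic transitions on a
        # 100-bp background kept conserved so column resampling cannot
        # saturate the K2P correction
        base = list("ACGT" * 25)
        left = "".join(base)
        right_chars = list(base)
        for pos in range(0, 40, 4):  # 10 A->G transitions
            right_chars[pos] = "G"
        right = "".join(right_chars)

        def private(seq, pos, alt):
            chars = list(seq)
            chars[pos] = alt
            return "".join(chars)

        seqs = [
            left,
            private(left, 50, "G"),
            private(left, 60, "T"),
            right,
            private(right, 70, "G"),
            private(right, 80, "T"),
        ]
        return AlignedSequenceSet(ids=tuple(f"t{i}" for i in range(6)), seqs=tuple(seqs))

    def test_strong_clade_high_support(self):
        tree = bootstrap_support(self._clade_alignment(), B=100, seed=4)
        split = frozenset(
            {frozenset({"t0", "t1", "t2"}), frozenset({"t3", "t4", "t5"})}
        )
        assert split in tree.supports
        assert tree.supports[split] >= 95.0

    def test_single_replicate_gives_binary_supports(self):
        tree = bootstrap_support(self._clade_alignment(), B=1, seed=5)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_unstructured_alignment_low_support(self, rng):
        # private mutations only (a star genealogy): internal bipartitions
        # are noise, supports mostly weak
        base = list("ACGT" * 30)
        transition = {"A": "G", "C": "T", "G": "A", "T": "C"}
        seqs = []
        for i in range(6):
            chars = list(base)
            for pos in rng.choice(120, size=5, replace=False):
                chars[pos] = transition[chars[pos]]
            seqs.append("".join(chars))
        aln = AlignedSequenceSet(
            ids=tuple(f"r{i}" for i in range(6)), seqs=tuple(seqs)
        )
        tree = bootstrap_support(aln, B=100, seed=6)
        assert np.mean([v < 70.0 for v in tree.supports.values()]) >= 0.5
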