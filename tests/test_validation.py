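"""Distance matrices, neighbor joining, Newick output, held-out enrichment."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

import geneconnectome as gc
from geneconnectome.validation import parse_newick


def random_additive_tree(n_taxa, rng):
    """Random unrooted binary tree as an edge-weighted adjacency; the path
    lengths between leaves form an additive distance matrix (independent
    oracle for NJ).  Returns (leaf labels, matrix, generating graph)."""
    import networkx as nx

    labels = [f"L{i:02d}" for i in range(n_taxa)]
    g = nx.Graph()
    center = "I0"
    g.add_edge(labels[0], center)
    g.add_edge(labels[1], center)
    g.add_edge(labels[2], center)
    internal = 1
    for leaf in labels[3:]:
        # attach the new leaf to a random existing edge via a new internal node
        edges = list(g.edges)
        a, b = edges[rng.integers(0, len(edges))]
        node = f"I{internal}"
        internal += 1
        g.remove_edge(a, b)
        g.add_edge(a, node)
        g.add_edge(node, b)
        g.add_edge(leaf, node)
    for a, b in g.edges:
        g.edges[a, b]["weight"] = float(rng.uniform(0.1, 5.0))
    dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    matrix = np.array([[dist[a][b] for b in labels] for a in labels])
    matrix = np.minimum(matrix, matrix.T)  # exact symmetry despite fp order
    return labels, matrix, g


def patristic_matrix(fga, labels):
    pdm = fga.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in fga.tree.taxon_namespace}
    return np.array(
        [[pdm.patristic_distance(taxa[a], taxa[b]) for b in labels] for a in labels]
    )


class TestDistanceMatrix:
    def test_zero_diagonal_and_symmetry(self, small_world):
        genes = sorted(small_world.network.genes)[:20]
        labels, mat = gc.distance_matrix(small_world.network, genes)
        assert np.array_equal(np.diag(mat), np.zeros(len(labels)))
        assert np.array_equal(mat, mat.T)

    def test_entries_match_shortest_route(self, small_world):
        net = small_world.network
        genes = sorted(net.genes)[:15]
        labels, mat = gc.distance_matrix(net, genes)
        rng = np.random.default_rng(8)
        for _ in range(30):
            i, j = rng.integers(0, len(labels), size=2)
            expected = gc.shortest_route(net, labels[i], labels[j]).distance
            assert mat[i, j] == pytest.approx(expected, abs=1e-9)

    def test_disconnected_genes_dropped_greedily(self, two_clique_net):
        genes = sorted(two_clique_net.genes)
        labels, mat = gc.distance_matrix(two_clique_net, genes)
        # one whole clique must go; the survivors are mutually reachable
        assert len(labels) == 5
        assert np.isfinite(mat).all()

    def test_too_few_genes_rejected(self, chain_net):
        with pytest.raises(gc.ParameterError):
            gc.distance_matrix(chain_net, ["A", "B"])

    def test_absent_genes_dropped(self, chain_net):
        labels, _ = gc.distance_matrix(chain_net, ["A", "B", "C", "GHOST"])
        assert labels == ["A", "B", "C"]


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        matrix = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = gc.nj_tree(matrix, ["A", "B", "C"])
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in tree.tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    @pytest.mark.parametrize("n_taxa", [4, 5, 8, 12])
    def test_additive_matrix_recovered_exactly(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        labels, matrix, _ = random_additive_tree(n_taxa, rng)
        tree = gc.nj_tree(matrix, labels)
        recovered = patristic_matrix(tree, labels)
        assert np.allclose(recovered, matrix, atol=1e-9)
        assert tree.leaf_labels() == set(labels)

    def test_topology_matches_independent_oracle(self):
        """NJ on a generic (non-additive) matrix must agree in topology with
        scikit-bio's canonical implementation."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(99)
        n = 8
        half = rng.uniform(1.0, 10.0, size=(n, n))
        matrix = np.triu(half, 1)
        matrix = matrix + matrix.T
        labels = [f"L{i}" for i in range(n)]
        mine = gc.to_newick(gc.nj_tree(matrix, labels))
        theirs = str(skbio_nj(DistanceMatrix(matrix, ids=labels)))
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=mine, schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=theirs, schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        assert treecompare.symmetric_difference(t1, t2) == 0

    def test_internal_nodes_are_degree_three(self):
        rng = np.random.default_rng(77)
        labels, matrix, _ = random_additive_tree(9, rng)
        tree = gc.nj_tree(matrix, labels)
        for node in tree.tree.preorder_node_iter():
            if node.is_leaf():
                continue
            degree = len(node.child_nodes()) + (0 if node.parent_node is None else 1)
            assert degree == 3

    def test_no_negative_branch_lengths(self):
        # strongly non-additive matrix provokes negative NJ estimates
        matrix = np.array(
            [[0, 2, 3, 9], [2, 0, 9, 3], [3, 9, 0, 2], [9, 3, 2, 0]], dtype=float
        )
        tree = gc.nj_tree(matrix, ["A", "B", "C", "D"])
        for edge in tree.tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0.0

    def test_asymmetric_matrix_rejected(self):
        matrix = np.array([[0, 2, 3], [2.1, 0, 4], [3, 4, 0]], dtype=float)
        with pytest.raises(gc.ParameterError, match="symmetric"):
            gc.nj_tree(matrix, ["A", "B", "C"])

    @pytest.mark.parametrize(
        "matrix,labels",
        [
            (np.zeros((2, 3)), ["A", "B"]),
            (np.zeros((3, 3)), ["A", "B"]),
            (np.zeros((3, 3)), ["A", "A", "B"]),
        ],
    )
    def test_malformed_input_rejected(self, matrix, labels):
        with pytest.raises(gc.ParameterError):
            gc.nj_tree(matrix, labels)

    def test_deterministic_under_ties(self):
        matrix = np.ones((4, 4)) - np.eye(4)
        labels = ["D", "C", "B", "A"]
        first = gc.to_newick(gc.nj_tree(matrix, labels))
        second = gc.to_newick(gc.nj_tree(matrix, labels))
        assert first == second


class TestNewick:
    def test_three_taxon_round_trip(self):
        matrix = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        text = gc.to_newick(gc.nj_tree(matrix, ["A", "B", "C"]))
        reparsed = parse_newick(text)
        lengths = {
            leaf.taxon.label: leaf.edge.length
            for leaf in reparsed.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    @pytest.mark.parametrize("seed", range(5))
    def test_leaf_set_preserved_for_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        labels, matrix, _ = random_additive_tree(10, rng)
        text = gc.to_newick(gc.nj_tree(matrix, labels))
        reparsed = parse_newick(text)
        assert {l.taxon.label for l in reparsed.leaf_node_iter()} == set(labels)

    def test_labels_with_spaces_are_quoted(self):
        matrix = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        text = gc.to_newick(gc.nj_tree(matrix, ["GENE ONE", "B", "C"]))
        assert "'GENE ONE'" in text
        reparsed = parse_newick(text)
        assert "GENE ONE" in {l.taxon.label for l in reparsed.leaf_node_iter()}


class TestHoldoutEnrichment:
    def test_every_background_gene_a_candidate_forces_p_one(self):
        bg = {f"G{i}" for i in range(30)}
        hold = set(list(bg)[:5])
        res = gc.holdout_enrichment_test(bg, hold, bg, n_sims=100, seed=0)
        assert res.k == res.n and res.p_exact == 1.0

    def test_zero_hits_tail_is_one(self):
        bg = {f"G{i}" for i in range(40)}
        cand = {g for g in bg if int(g[1:]) < 20}
        hold = {g for g in bg if int(g[1:]) >= 35}
        res = gc.holdout_enrichment_test(cand, hold, bg, n_sims=100, seed=0)
        assert res.k == 0 and res.p_exact == 1.0

    def test_holdout_outside_background_rejected(self):
        bg = {"A", "B", "C"}
        with pytest.raises(gc.ParameterError, match="GHOST"):
            gc.holdout_enrichment_test({"A"}, {"GHOST"}, bg, n_sims=10, seed=0)

    def test_empirical_converges_to_exact(self):
        rng = np.random.default_rng(3)
        bg = {f"G{i:03d}" for i in range(200)}
        cand = {g for g in bg if int(g[1:]) < 60}
        hold = set(rng.choice(sorted(bg), size=15, replace=False))
        res = gc.holdout_enrichment_test(cand, hold, bg, n_sims=40_000, seed=5)
        se = math.sqrt(res.p_exact * (1 - res.p_exact) / res.n_sims)
        assert abs(res.p_empirical - res.p_exact) <= 3 * se + 1e-12

    def test_marginal_and_subset_sampling_agree(self):
        bg = {f"G{i:03d}" for i in range(120)}
        cand = {g for g in bg if int(g[1:]) < 40}
        hold = {g for g in bg if int(g[1:]) % 11 == 0}
        a = gc.holdout_enrichment_test(
            cand, hold, bg, n_sims=20_000, seed=7, method="marginal"
        )
        b = gc.holdout_enrichment_test(
            cand, hold, bg, n_sims=20_000, seed=7, method="subsets"
        )
        assert a.p_exact == b.p_exact
        se = math.sqrt(max(a.p_exact * (1 - a.p_exact), 1e-12) / 20_000)
        assert abs(a.p_empirical - b.p_empirical) <= 6 * se

    def test_deterministic_given_seed(self):
        bg = {f"G{i}" for i in range(50)}
        cand = {g for g in bg if int(g[1:]) < 20}
        hold = {g for g in bg if int(g[1:]) % 7 == 0}
        r1 = gc.holdout_enrichment_test(cand, hold, bg, n_sims=5_000, seed=11)
        r2 = gc.holdout_enrichment_test(cand, hold, bg, n_sims=5_000, seed=11)
        assert r1 == r2
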