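"""Pan-genome alignment scoring, MCL families, categories and NJ tree."""

import dendropy
import numpy as np
import pytest
from Bio.Align import substitution_matrices

from tssline.pangenome import (
    PanGenomeResult,
    SimilarityGraph,
    categorize_families,
    evalue_proxy,
    mcl_cluster,
    neighbor_joining,
    pan_distance_matrix,
    pan_genome_pipeline,
    score_pairs,
)
from tssline.simulate import SimulationConfig, generate_proteomes

BLOSUM62 = substitution_matrices.load("BLOSUM62")
AMINO = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, length):
    return "".join(rng.choice(list(AMINO), size=length))


class TestScoring:
    def test_identical_sequence_scores_blosum_diagonal_sum(self):
        rng = np.random.default_rng(0)
        seq = _random_protein(rng, 120)
        graph = score_pairs({"a": [("a|p1", seq)], "b": [("b|p1", seq)]})
        assert len(graph.edges) == 1
        expected = sum(BLOSUM62[c, c] for c in seq)
        assert graph.edges[0][2] == pytest.approx(expected)

    def test_unrelated_random_pairs_rarely_edge(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a, b = _random_protein(rng, 50), _random_protein(rng, 50)
            graph = score_pairs({"a": [("a|p", a)], "b": [("b|p", b)]})
            hits += bool(graph.edges)
        assert hits <= 1  # >= 95% of unrelated pairs rejected

    def test_evalue_decreases_with_score_and_increases_with_length(self):
        assert evalue_proxy(100, 100, 100) < evalue_proxy(60, 100, 100)
        assert evalue_proxy(100, 100, 100) < evalue_proxy(100, 500, 500)

    def test_single_genome_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            score_pairs({"a": [("a|p", "MKV")]})

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError, match="empty proteome"):
            score_pairs({"a": [("a|p", "MKV" * 30)], "b": []})


def _graph(n_nodes, edges, weight=100.0):
    nodes = [f"g{i}|p{i}" for i in range(n_nodes)]
    return SimilarityGraph(nodes=nodes,
                           edges=[(i, j, weight) for i, j in edges])


class TestMCL:
    def test_two_triangles_two_families(self):
        graph = _graph(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        fams = mcl_cluster(graph)
        members = sorted(sorted(int(p.split("p")[1]) for p in f) for f in fams)
        assert members == [[0, 1, 2], [3, 4, 5]]

    def test_weakly_bridged_cliques_split(self):
        edges = [(i, j) for i in range(5) for j in range(i + 1, 5)]
        edges += [(i + 5, j + 5) for i, j in
                  [(a, b) for a in range(5) for b in range(a + 1, 5)]]
        graph = _graph(10, edges, weight=50.0)
        graph.edges.append((4, 5, 1.0))  # weak bridge
        fams = mcl_cluster(graph, inflation=1.5)
        sizes = sorted(len(f) for f in fams)
        assert sizes == [5, 5]

    def test_isolated_node_is_singleton_family(self):
        graph = _graph(3, [(0, 1)])
        fams = mcl_cluster(graph)
        assert sorted(len(f) for f in fams) == [1, 2]

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mcl_cluster(SimilarityGraph(nodes=[], edges=[]))


class TestCategories:
    GENOMES = ["gA", "gB", "gC"]

    def test_core_dispensable_unique(self):
        fams = [["gA|x", "gB|x", "gC|x"],   # core
                ["gA|y", "gB|y"],           # dispensable
                ["gC|z"]]                   # unique
        res = categorize_families(fams, self.GENOMES)
        assert res.category == ["core", "dispensable", "unique"]
        assert res.family_counts() == {"core": 1, "dispensable": 1, "unique": 1}
        assert res.gene_counts() == {"core": 3, "dispensable": 2, "unique": 1}

    def test_paralogs_count_once_for_span(self):
        fams = [["gA|x1", "gA|x2", "gB|x", "gC|x"]]
        res = categorize_families(fams, self.GENOMES)
        assert res.category == ["core"]
        assert res.gene_counts()["core"] == 4

    def test_totals_conserved(self):
        fams = [["gA|a", "gB|a"], ["gB|b"], ["gA|c", "gB|c", "gC|c"]]
        res = categorize_families(fams, self.GENOMES)
        assert sum(res.gene_counts().values()) == sum(map(len, fams))
        per_genome = res.per_genome_gene_counts()
        assert sum(sum(v.values()) for v in per_genome.values()) == sum(map(len, fams))

    def test_unknown_genome_rejected(self):
        with pytest.raises(ValueError, match="unknown genome"):
            categorize_families([["gZ|p"]], self.GENOMES)


class TestDistances:
    def test_identical_and_disjoint_repertoires(self):
        res = categorize_families(
            [["gA|x", "gB|x"], ["gA|y", "gB|y"]], ["gA", "gB"])
        D = pan_distance_matrix(res)
        assert D[0, 1] == 0.0
        res2 = categorize_families([["gA|x"], ["gB|y"]], ["gA", "gB"])
        D2 = pan_distance_matrix(res2)
        assert D2[0, 1] == 1.0

    def test_symmetry_and_zero_diagonal(self):
        res = categorize_families(
            [["gA|x", "gB|x", "gC|x"], ["gA|y"], ["gB|z", "gC|z"]],
            ["gA", "gB", "gC"])
        D = pan_distance_matrix(res)
        assert np.allclose(D, D.T) and np.allclose(np.diag(D), 0)


class TestNeighborJoining:
    def test_additive_four_taxon_tree_recovered(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) -> additive distances
        D = np.array([
            [0, 5, 7, 8],
            [5, 0, 8, 9],
            [7, 8, 0, 9],
            [8, 9, 9, 0],
        ], dtype=float)
        newick, clamped = neighbor_joining(D, ["A", "B", "C", "D"])
        assert clamped == 0
        tree = dendropy.Tree.get(data=newick, schema="newick")
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        names = ["A", "B", "C", "D"]
        for a in range(4):
            for b in range(a + 1, 4):
                got = pdm.distance(taxa[names[a]], taxa[names[b]])
                assert got == pytest.approx(D[a, b], abs=1e-9)

    def test_three_taxon_exact_branches(self):
        D = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]], dtype=float)
        newick, clamped = neighbor_joining(D, ["A", "B", "C"])
        assert clamped == 0
        tree = dendropy.Tree.get(data=newick, schema="newick")
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(1.0)

    def test_leaves_conserved(self):
        rng = np.random.default_rng(1)
        n = 7
        X = rng.random((n, 3))
        D = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
        names = [f"t{i}" for i in range(n)]
        newick, _ = neighbor_joining(D, names)
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == names

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [3, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(D, ["A", "B", "C"])

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(np.zeros((2, 2)), ["A", "B"])


class TestPipelineOnSynthetic:
    def test_generated_families_recovered(self):
        cfg = SimulationConfig(seed=2)
        proteomes, truth = generate_proteomes(cfg, n_genomes=4, n_families=30)
        result = pan_genome_pipeline(proteomes)
        # category of each protein matches its family's planted category
        truth_cat = {pid: truth.family_category[fam]
                     for pid, fam in truth.family_assignment.items()}
        correct = sum(
            truth_cat[pid] == cat
            for fam, cat in zip(result.families, result.category)
            for pid in fam)
        total = sum(map(len, result.families))
        assert correct / total >= 0.95
        assert result.tree_newick and result.tree_newick.endswith(";")
        counts = result.family_counts()
        assert sum(counts.values()) == len(result.families)
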