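import numpy as np
import pytest

from zooregion.incidence import AdjacencyGraph, IncidenceMatrix
from zooregion.pae import (
    ROOT_TAXON,
    PAEMatrix,
    Tree,
    consensus_to_newick,
    exhaustive_search,
    extract_aoes,
    fitch_length,
    heuristic_search,
    prepare_pae_matrix,
    strict_consensus,
)

from .oracles import exhaustive_parsimony_min


def tree_from_splits(n_leaves, groups):
    """Build an unrooted binary tree by sequential grouping; ``groups`` is a
    list of leaf-index pairs to cherry together, e.g. [(0,1),(2,3)]."""
    t = Tree.initial(0, 1, 2, n_leaves)
    for leaf in range(3, n_leaves):
        t = t.attach_leaf(leaf, t.edges()[0])
    return t


def balanced_quartet(a, b, c, d):
    """Unrooted 4-taxon tree ((a,b),(c,d))."""
    adj = {a: {4}, b: {4}, 4: {a, b, 5}, 5: {4, c, d}, c: {5}, d: {5}}
    return Tree(4, adj)


class TestPrepare:
    def test_singleton_removed_kept_in_report(self, five_ogu_matrix):
        pm, report = prepare_pae_matrix(five_ogu_matrix)
        assert "s3" not in pm.characters
        assert report.singleton_species == {"s3": "A"}
        assert pm.taxa[-1] == ROOT_TAXON
        assert (pm.matrix[-1] == 0).all()

    def test_all_multi_ogu_characters_unchanged(self):
        cells = np.array([[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 1, 1]], dtype=np.int8)
        m = IncidenceMatrix(["a", "b", "c"], list("ABCD"), cells)
        pm, _ = prepare_pae_matrix(m)
        assert pm.characters == ["a", "b", "c"]

    def test_too_few_taxa_errors(self):
        m = IncidenceMatrix(["a"], ["A", "B", "C"], np.array([[1, 1, 1]]))
        with pytest.raises(ValueError, match="at least 4"):
            prepare_pae_matrix(m)

    def test_nexus_export(self, five_ogu_matrix):
        pm, _ = prepare_pae_matrix(five_ogu_matrix)
        nexus = pm.to_nexus()
        assert "#NEXUS" in nexus and f"NTAX={len(pm.taxa)}" in nexus


class TestFitchLength:
    def test_single_origin_one_step(self):
        t = balanced_quartet(0, 1, 2, 3)
        char = np.array([[1], [1], [0], [0]])
        assert fitch_length(t, char) == 1

    def test_split_character_two_steps(self):
        # same character on ((A,C),(B,D))
        t = balanced_quartet(0, 2, 1, 3)
        char = np.array([[1], [1], [0], [0]])
        assert fitch_length(t, char) == 2

    def test_all_zero_character_zero_steps(self):
        t = balanced_quartet(0, 1, 2, 3)
        assert fitch_length(t, np.zeros((4, 1), dtype=int)) == 0

    def test_leaf_mismatch_errors(self):
        t = balanced_quartet(0, 1, 2, 3)
        with pytest.raises(ValueError):
            fitch_length(t, np.zeros((5, 1), dtype=int))

    def test_matches_oracle_on_random_trees(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = 6
            matrix = (rng.random((n, 4)) < 0.5).astype(int)
            res = exhaustive_search(PAEMatrix([f"t{i}" for i in range(n)],
                                              list("wxyz"), matrix))
            assert res.best_length == exhaustive_parsimony_min(matrix)


class TestHeuristicSearch:
    def test_equals_exhaustive_on_six_taxa(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            matrix = (rng.random((6, 5)) < 0.5).astype(int)
            pm = PAEMatrix([f"t{i}" for i in range(6)],
                           [f"c{j}" for j in range(5)], matrix)
            heur = heuristic_search(pm, n_replicates=3, seed=7)
            assert heur.best_length == exhaustive_parsimony_min(matrix)

    def test_compatible_matrix_no_homoplasy(self):
        # perfectly nested characters: one step each
        matrix = np.array(
            [
                [1, 1, 0],
                [1, 1, 0],
                [1, 0, 0],
                [0, 0, 1],
                [0, 0, 1],
            ]
        )
        pm = PAEMatrix([f"t{i}" for i in range(5)], list("abc"), matrix)
        res = heuristic_search(pm, n_replicates=3, seed=0)
        assert res.best_length == 3

    def test_deterministic_for_seed(self):
        rng = np.random.default_rng(2)
        matrix = (rng.random((6, 6)) < 0.5).astype(int)
        pm = PAEMatrix([f"t{i}" for i in range(6)], [f"c{j}" for j in range(6)], matrix)
        r1 = heuristic_search(pm, n_replicates=2, seed=5)
        r2 = heuristic_search(pm, n_replicates=2, seed=5)
        assert r1.best_length == r2.best_length
        assert r1.topologies == r2.topologies

    def test_best_not_worse_than_any_candidate_tree(self):
        rng = np.random.default_rng(3)
        matrix = (rng.random((6, 5)) < 0.5).astype(int)
        pm = PAEMatrix([f"t{i}" for i in range(6)], [f"c{j}" for j in range(5)], matrix)
        res = heuristic_search(pm, n_replicates=2, seed=1)
        user_tree = tree_from_splits(6, None)
        assert res.best_length <= fitch_length(user_tree, matrix)


class TestStrictConsensus:
    def test_identical_trees(self):
        t = balanced_quartet(0, 1, 2, 3)
        assert strict_consensus([t, t.copy()]) == t.bipartitions()

    def test_shared_clade_only(self):
        # 5 taxa: tree1 = ((0,1),(2,3),4); tree2 = ((0,1),(2,4),3)
        def five_tree(pair2):
            a, b = pair2
            rest = [x for x in (2, 3, 4) if x not in pair2]
            adj = {
                0: {5}, 1: {5}, 5: {0, 1, 6},
                a: {7}, b: {7}, 7: {a, b, 6},
                6: {5, 7, rest[0]}, rest[0]: {6},
            }
            return Tree(5, adj)

        t1 = five_tree((2, 3))
        t2 = five_tree((2, 4))
        common = strict_consensus([t1, t2])
        sides = {frozenset(s) for s in common}
        # only the (0,1) split survives; expressed from the side without leaf 0
        assert sides == {frozenset({2, 3, 4})}

    def test_incompatible_pair_star(self):
        t1 = balanced_quartet(0, 1, 2, 3)
        t2 = balanced_quartet(0, 2, 1, 3)
        assert strict_consensus([t1, t2]) == set()

    def test_leaf_mismatch_errors(self):
        t1 = balanced_quartet(0, 1, 2, 3)
        t2 = Tree.initial(0, 1, 2, 3)
        with pytest.raises(ValueError, match="mismatch"):
            strict_consensus([t1, t2])

    def test_consensus_subset_of_inputs(self):
        rng = np.random.default_rng(4)
        matrix = (rng.random((6, 5)) < 0.5).astype(int)
        pm = PAEMatrix([f"t{i}" for i in range(6)], [f"c{j}" for j in range(5)], matrix)
        res = heuristic_search(pm, n_replicates=4, seed=9)
        common = strict_consensus(res.trees)
        for t in res.trees:
            assert common <= t.bipartitions()

    def test_newick_render(self):
        t = balanced_quartet(0, 1, 2, 3)
        taxa = ["A", "B", "C", ROOT_TAXON]
        nwk = consensus_to_newick(strict_consensus([t]), taxa)
        assert nwk.startswith(f"({ROOT_TAXON},") and nwk.endswith(";")
        assert "(A,B)" in nwk


class TestExtractAoes:
    def _graph(self):
        return AdjacencyGraph(list("ABCDE"),
                              [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])

    def test_contiguous_clade_with_sympatric_endemics(self, five_ogu_matrix):
        g = self._graph()
        clade = frozenset({0, 1})  # indices of D, E in taxa below
        taxa = ["D", "E", "A", ROOT_TAXON]
        aoes = extract_aoes({clade}, taxa, five_ogu_matrix, g)
        pair = [a for a in aoes if a.members == frozenset("DE")]
        assert pair and set(pair[0].supporting_species) == {"s5", "s6"}

    def test_sympatry_required(self):
        # two endemics of {A,B} that never co-occur
        cells = np.array([[1, 0, 0], [0, 1, 0], [1, 1, 1]], dtype=np.int8)
        m = IncidenceMatrix(["e1", "e2", "w"], list("ABC"), cells)
        g = AdjacencyGraph(list("ABC"), [("A", "B"), ("B", "C")])
        taxa = ["A", "B", ROOT_TAXON]
        aoes = extract_aoes({frozenset({0, 1})}, taxa, m, g)
        assert all(a.members != frozenset("AB") for a in aoes)

    def test_non_contiguous_clade_rejected(self):
        cells = np.array([[1, 0, 1], [1, 0, 1]], dtype=np.int8)
        m = IncidenceMatrix(["e1", "e2"], list("ABC"), cells)
        g = AdjacencyGraph(list("ABC"), [("A", "B"), ("B", "C")])
        taxa = ["A", "C", ROOT_TAXON]
        aoes = extract_aoes({frozenset({0, 1})}, taxa, m, g)
        assert all(a.provenance != "consensus_clade" for a in aoes)

    def test_singleton_ogu_aoe(self):
        cells = np.array([[1, 0], [1, 0], [0, 1]], dtype=np.int8)
        m = IncidenceMatrix(["n1", "n2", "x"], ["A", "B"], cells)
        g = AdjacencyGraph(["A", "B"], [("A", "B")])
        aoes = extract_aoes(set(), ["A", "B", ROOT_TAXON], m, g,
                            singleton_report={"n1": "A", "n2": "A"})
        assert len(aoes) == 1
        assert aoes[0].members == frozenset("A")
        assert aoes[0].provenance == "singleton_ogu"

    def test_supporting_species_do_not_span_outside(self, five_ogu_matrix):
        g = self._graph()
        taxa = ["D", "E", "A", ROOT_TAXON]
        aoes = extract_aoes({frozenset({0, 1})}, taxa, five_ogu_matrix, g)
        for a in aoes:
            for sid in a.supporting_species:
                assert five_ogu_matrix.range_of(sid) <= a.members
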