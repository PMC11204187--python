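"""Tree space: enumeration counts, move neighborhoods, exact and heuristic
search, collapsing."""

import random

import numpy as np
import pytest

from fitchclad import (
    MISSING,
    CharacterMatrix,
    SearchConfig,
    Tree,
    branch_and_bound,
    collapse_min_length_zero,
    enumerate_topologies,
    fitch_length,
    heuristic_search,
    neighbors,
    perfect_matrix,
    random_tree,
)

from conftest import random_matrix


def double_factorial(k):
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


class TestEnumeration:
    @pytest.mark.parametrize("n", [4, 5, 6, 7])
    def test_count_is_double_factorial(self, n):
        taxa = [f"t{i}" for i in range(n)]
        trees = list(enumerate_topologies(taxa))
        assert len(trees) == double_factorial(2 * n - 5)
        assert len({t.canonical_key() for t in trees}) == len(trees)

    def test_all_binary(self):
        for t in enumerate_topologies(list("abcde")):
            assert t.is_binary()

    def test_guard(self):
        with pytest.raises(ValueError):
            list(enumerate_topologies(["a", "b"]))
        with pytest.raises(ValueError):
            list(enumerate_topologies([f"t{i}" for i in range(11)]))


class TestNeighborhoods:
    def test_nni_count_quartet(self, quartet):
        assert len(list(neighbors(quartet, "nni"))) == 2

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_nni_count_formula(self, n):
        tree = random_tree(n, seed=n)
        assert len(list(neighbors(tree, "nni"))) == 2 * (n - 3)

    @pytest.mark.parametrize("n", [6, 7])
    def test_move_containment(self, n):
        tree = random_tree(n, seed=100 + n)
        nni = {t.canonical_key() for t in neighbors(tree, "nni")}
        spr = {t.canonical_key() for t in neighbors(tree, "spr")}
        tbr = {t.canonical_key() for t in neighbors(tree, "tbr")}
        assert nni <= spr <= tbr
        assert tree.canonical_key() not in tbr

    def test_neighbors_are_valid_binary_trees(self):
        tree = random_tree(6, seed=1)
        for t in neighbors(tree, "tbr"):
            assert t.is_binary() and t.leaves == tree.leaves

    def test_non_binary_rejected(self):
        star = Tree.from_clusters(list("abcde"), [])
        with pytest.raises(Exception, match="binary"):
            list(neighbors(star, "nni"))


class TestBranchAndBound:
    def test_quartet_matches_exhaustive(self):
        rng = random.Random(2)
        for _ in range(10):
            m = random_matrix(rng, 4, 6, missing_frac=0.1)
            exact = branch_and_bound(m)
            scored = [
                (fitch_length(t, m)[0], t) for t in enumerate_topologies(m.taxa)
            ]
            best = min(s for s, _ in scored)
            best_set = {t.canonical_key() for s, t in scored if s == best}
            assert exact.score == best
            assert {t.canonical_key() for t in exact.trees} == best_set

    def test_seven_taxon_oracle_equivalence(self):
        rng = random.Random(77)
        for _ in range(12):
            m = random_matrix(rng, 7, 8, missing_frac=0.15)
            exact = branch_and_bound(m)
            scored = [
                (fitch_length(t, m)[0], t) for t in enumerate_topologies(m.taxa)
            ]
            best = min(s for s, _ in scored)
            assert exact.score == best
            assert {t.canonical_key() for t in exact.trees} == {
                t.canonical_key() for s, t in scored if s == best
            }
            assert exact.exact and not exact.capped

    def test_max_trees_cap_flag(self):
        # a constant matrix scores zero on every topology
        m = CharacterMatrix(list("abcdef"), np.zeros((6, 3), dtype=np.int8))
        capped = branch_and_bound(m, max_trees=10)
        assert capped.score == 0
        assert len(capped.trees) == 10 and capped.capped

    def test_guard(self):
        m = CharacterMatrix(
            [f"t{i}" for i in range(17)], np.zeros((17, 2), dtype=np.int8)
        )
        with pytest.raises(ValueError, match="16"):
            branch_and_bound(m)


class TestHeuristicSearch:
    def test_matches_exact_on_perfect_matrix(self):
        tree = random_tree(9, seed=4)
        m = perfect_matrix(tree)
        result = heuristic_search(m, SearchConfig(seed=5, n_replicates=5))
        assert result.score == m.n_chars
        assert any(t == tree for t in result.trees)

    def test_admissibility_and_usual_equality(self):
        rng = random.Random(123)
        hits = 0
        trials = 25
        for _ in range(trials):
            m = random_matrix(rng, 8, 10, missing_frac=0.1)
            exact = branch_and_bound(m)
            heur = heuristic_search(
                m, SearchConfig(seed=rng.randrange(10**6), n_replicates=5)
            )
            assert heur.score >= exact.score
            hits += heur.score == exact.score
        assert hits >= 0.9 * trials

    def test_determinism(self, matrix):
        config = SearchConfig(seed=99, n_replicates=3)
        a = heuristic_search(matrix, config)
        b = heuristic_search(matrix, config)
        assert a.score == b.score
        assert [t.newick() for t in a.trees] == [t.newick() for t in b.trees]

    def test_constant_matrix_all_trees_optimal_capped(self):
        m = CharacterMatrix(list("abcdefg"), np.zeros((7, 1), dtype=np.int8))
        result = heuristic_search(
            m, SearchConfig(seed=1, n_replicates=2, max_trees=20)
        )
        assert result.score == 0
        assert len(result.trees) == 20 and result.capped


class TestCollapse:
    def test_perfect_matrix_collapses_nothing(self):
        tree = random_tree(7, seed=8)
        m = perfect_matrix(tree)
        assert collapse_min_length_zero(tree, m) == tree

    def test_constant_matrix_collapses_to_star(self):
        m = CharacterMatrix(list("abcdef"), np.zeros((6, 2), dtype=np.int8))
        tree = random_tree(6, seed=3, labels=list("abcdef"))
        collapsed = collapse_min_length_zero(tree, m)
        assert len(collapsed.bipartitions()) == 0

    def test_bundled_mpts_dedupe_after_collapse(self, matrix, mpts):
        collapsed = {
            collapse_min_length_zero(t, matrix).canonical_key()
            for t in mpts.trees
        }
        assert 0 < len(collapsed) < len(mpts.trees)
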