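"""Fitch engine: oracle equivalence, step bounds, reconstructions."""

import random

import numpy as np
import pytest

from fitchclad import (
    MISSING,
    CharacterMatrix,
    Tree,
    ancestral_states,
    brute_force_length,
    enumerate_topologies,
    fitch_length,
    max_steps,
    min_steps,
)

from conftest import random_matrix


def column_of(matrix, j):
    return dict(zip(matrix.taxa, (int(s) for s in matrix.column(j))))


class TestStepBounds:
    def test_character_3_of_study_matrix(self, matrix):
        # four observed states in the oblique-vein character
        assert min_steps(matrix.column(3)) == 3

    def test_all_missing_column(self):
        col = [MISSING, MISSING, MISSING]
        assert min_steps(col) == 0 and max_steps(col) == 0

    def test_binary_column_counts(self):
        col = [0, 0, 0, 0, 1, 1, 1]
        assert min_steps(col) == 1
        assert max_steps(col) == 3

    def test_sandwich_on_random_instances(self):
        rng = random.Random(5)
        for _ in range(30):
            n = rng.randrange(4, 7)
            m = random_matrix(rng, n, 6, missing_frac=0.2)
            tree = next(enumerate_topologies(m.taxa))
            _, fits = fitch_length(tree, m)
            for fit in fits:
                assert fit.m <= fit.s <= fit.g
                assert 0.0 <= fit.ci <= 1.0
                assert 0.0 <= fit.ri <= 1.0


class TestFitchLength:
    def test_constant_character_is_free(self, quartet):
        m = CharacterMatrix(["a", "b", "c", "d"], np.zeros((4, 1), dtype=np.int8))
        total, fits = fitch_length(quartet, m)
        assert total == 0 and fits[0].s == 0 and fits[0].ci == 1.0

    def test_quartet_single_change(self, quartet):
        m = CharacterMatrix(["a", "b", "c", "d"], np.array([[0], [0], [1], [1]]))
        total, _ = fitch_length(quartet, m)
        assert total == 1

    def test_missing_leaf_never_costs(self, quartet):
        m = CharacterMatrix(
            ["a", "b", "c", "d"], np.array([[0], [0], [MISSING], [0]])
        )
        total, _ = fitch_length(quartet, m)
        assert total == 0

    def test_root_invariance(self):
        rng = random.Random(9)
        m = random_matrix(rng, 6, 8, missing_frac=0.1)
        tree = list(enumerate_topologies(m.taxa))[33]
        from fitchclad.fitch import _column_masks, _fitch_steps

        for j in range(1, m.n_chars + 1):
            masks = _column_masks(m, j)
            scores = {
                _fitch_steps(tree, masks, root) for root in m.taxa
            }
            assert len(scores) == 1

    def test_column_permutation_invariance(self):
        rng = random.Random(3)
        m = random_matrix(rng, 6, 10, missing_frac=0.1)
        tree = next(enumerate_topologies(m.taxa))
        perm = list(range(1, 11))
        rng.shuffle(perm)
        permuted = m.subset_columns(perm)
        assert fitch_length(tree, m)[0] == fitch_length(tree, permuted)[0]

    def test_polytomy_rejected(self, matrix):
        star = Tree.from_clusters(matrix.taxa, [])
        with pytest.raises(Exception, match="binary|resolved"):
            fitch_length(star, matrix)

    def test_unknown_leaf_rejected(self, matrix):
        t = Tree.from_newick("((nope,b),(c,d));")
        with pytest.raises(KeyError):
            fitch_length(t, matrix)

    def test_oracle_agreement_random_5_taxon(self):
        rng = random.Random(17)
        taxa = [f"t{i}" for i in range(5)]
        trees = list(enumerate_topologies(taxa))
        for _ in range(20):
            tree = rng.choice(trees)
            m = random_matrix(rng, 5, 1, n_states=4, missing_frac=0.2)
            total, _ = fitch_length(tree, m)
            assert total == brute_force_length(tree, column_of(m, 1))


class TestBruteForce:
    def test_constant_column(self, quartet):
        assert brute_force_length(quartet, dict.fromkeys("abcd", 0)) == 0

    def test_quartet_split_column(self, quartet):
        col = {"a": 0, "b": 0, "c": 1, "d": 1}
        assert brute_force_length(quartet, col) == 1

    def test_size_guard(self):
        taxa = [f"t{i}" for i in range(9)]
        tree = next(enumerate_topologies(taxa[:8]))
        # fine at 8 leaves ...
        brute_force_length(tree, dict.fromkeys(taxa[:8], 0))
        big = Tree.from_clusters(taxa, [])
        with pytest.raises(ValueError, match="8"):
            brute_force_length(big, dict.fromkeys(taxa, 0))


class TestAncestralStates:
    def test_constant_character_all_policies_agree(self, quartet):
        m = CharacterMatrix(["a", "b", "c", "d"], np.full((4, 1), 2, dtype=np.int8))
        for policy in ("acctran", "deltran", "unambiguous"):
            rec = ancestral_states(quartet, m, 1, policy)
            assert rec.steps == 0 and not rec.changes
            assert all(states == frozenset({2}) for states in rec.states.values())

    def test_change_counts_match_fitch(self):
        rng = random.Random(23)
        for _ in range(15):
            n = rng.randrange(4, 7)
            m = random_matrix(rng, n, 4, missing_frac=0.15)
            trees = list(enumerate_topologies(m.taxa))
            tree = rng.choice(trees)
            _, fits = fitch_length(tree, m)
            for j in range(1, m.n_chars + 1):
                for policy in ("acctran", "deltran"):
                    rec = ancestral_states(tree, m, j, policy)
                    assert len(rec.changes) == fits[j - 1].s

    def test_unambiguous_is_superset_of_either_walk(self):
        rng = random.Random(31)
        m = random_matrix(rng, 6, 5)
        tree = list(enumerate_topologies(m.taxa))[50]
        for j in range(1, 6):
            amb = ancestral_states(tree, m, j, "unambiguous")
            for policy in ("acctran", "deltran"):
                rec = ancestral_states(tree, m, j, policy)
                for clade, states in rec.states.items():
                    assert states <= amb.states[clade]

    def test_invalid_policy(self, quartet):
        m = CharacterMatrix(["a", "b", "c", "d"], np.zeros((4, 1), dtype=np.int8))
        with pytest.raises(ValueError, match="policy"):
            ancestral_states(quartet, m, 1, "fancy")

    def test_archaboilinae_gains_state_one_of_character_1(self, matrix, mpts):
        # the subfamily-defining wing-vein character changes 0 -> 1 exactly
        # once, on the branch subtending the ten-species clade
        from fitchclad import bundled_groups

        clade = frozenset(bundled_groups()["Archaboilinae"].members)
        tree = mpts.trees[0]
        rec = ancestral_states(
            tree, matrix, 1, "acctran", root_taxon="Euhagla saurensis"
        )
        assert len(rec.changes) == 1
        (change,) = rec.changes
        assert change.clade == clade
        assert change.to_states == frozenset({1})
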