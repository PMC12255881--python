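"""Trees, path-length matrices, their validation and interconversion."""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bmephylo import (DistanceMatrix, PartialTree, bme_length,
                      canonical_signature, enumerate_ubts,
                      generalized_tree_length, num_ubts, plm_to_tree,
                      read_newick, tree_to_plm, validate_plm, write_newick)
from bmephylo.tree import TreeStructureError, UnrootedBinaryTree

from conftest import random_dm


def bfs_leaf_distances(tree):
    """Independent BFS oracle for leaf-to-leaf edge counts."""
    n = tree.n
    out = np.zeros((n, n), dtype=int)
    for src in range(n):
        dist = {src: 0}
        q = deque([src])
        while q:
            u = q.popleft()
            for v in sorted(tree.adjacency[u]):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        out[src] = [dist[leaf] for leaf in range(n)]
    return out


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(3, 1), (4, 3), (5, 15), (6, 105),
                                         (7, 945)])
    def test_double_factorial_counts(self, n, count):
        assert num_ubts(n) == count
        assert sum(1 for _ in enumerate_ubts(n)) == count

    def test_all_plms_distinct(self):
        plms = {tree_to_plm(t) for t in enumerate_ubts(6)}
        assert len(plms) == 105

    def test_guard(self):
        with pytest.raises(ValueError, match="3 <= n <= 9"):
            list(enumerate_ubts(10))
        with pytest.raises(ValueError):
            list(enumerate_ubts(2))


class TestTreeToPlm:
    def test_three_leaf_star(self):
        t = next(enumerate_ubts(3))
        assert np.array_equal(
            tree_to_plm(t).values, np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]]))

    def test_quartet(self, quartet_plm):
        for t in enumerate_ubts(4):
            if t.splits() == frozenset({frozenset({2, 3})}):
                assert np.array_equal(tree_to_plm(t).values, quartet_plm)

    def test_matches_bfs_oracle_n6(self):
        for t in enumerate_ubts(6):
            assert np.array_equal(tree_to_plm(t).values,
                                  bfs_leaf_distances(t))

    def test_malformed_tree_rejected(self):
        # a degree-2 internal node
        adj = {0: {3}, 1: {3}, 2: {4}, 3: {0, 1, 4}, 4: {2, 3}}
        with pytest.raises(TreeStructureError, match="node 4"):
            UnrootedBinaryTree(adj)


class TestValidatePlm:
    def test_all_twos_fails_kraft(self):
        m = np.full((4, 4), 2)
        np.fill_diagonal(m, 0)
        rep = validate_plm(m)
        assert not rep.valid and not rep.kraft_ok
        # row sum of 2**-tau is 3/4, not 1/2
        assert any("0.75" in msg for msg in rep.messages)

    def test_quartet_plm_valid(self, quartet_plm):
        rep = validate_plm(quartet_plm)
        assert rep.valid
        # Kraft: 1/4 + 1/8 + 1/8 = 1/2; manifold: 2n-3 = 5
        pow2 = np.exp2(-quartet_plm.astype(float))
        np.fill_diagonal(pow2, 0)
        assert pow2.sum(axis=1).tolist() == [0.5] * 4
        assert (quartet_plm * pow2).sum() == 5

    def test_accepts_exactly_the_enumerated_plms_n6(self):
        valid = [tree_to_plm(t).values for t in enumerate_ubts(6)]
        assert all(validate_plm(m).valid for m in valid)

    def test_rejects_single_entry_perturbations(self):
        m = tree_to_plm(next(enumerate_ubts(6))).values.copy()
        for delta in (+1, -1):
            bad = m.copy()
            bad[0, 1] += delta  # breaks symmetry
            assert not validate_plm(bad).valid
            bad = m.copy()
            bad[0, 1] += delta
            bad[1, 0] += delta  # symmetric perturbation breaks Kraft
            assert not validate_plm(bad).kraft_ok or not validate_plm(bad).valid

    def test_kraft_and_manifold_for_all_small_trees(self):
        for n in range(3, 8):
            for t in enumerate_ubts(n):
                tau = tree_to_plm(t).values
                pow2 = np.exp2(-tau.astype(float))
                np.fill_diagonal(pow2, 0)
                assert np.all(pow2.sum(axis=1) == 0.5)
                assert (tau * pow2).sum() == 2 * n - 3

    def test_four_point_trichotomy_exhaustive_n6(self):
        from itertools import combinations
        for t in enumerate_ubts(6):
            tau = tree_to_plm(t).values
            for j, p, q in combinations(range(1, 6), 3):
                s = sorted([tau[0, j] + tau[p, q], tau[0, p] + tau[j, q],
                            tau[0, q] + tau[j, p]])
                assert s[1] == s[2] and s[0] + 2 <= s[1]

    def test_input_errors(self):
        with pytest.raises(ValueError):
            validate_plm(np.zeros((3, 4)))
        assert not validate_plm(np.full((4, 4), 2.5) -
                                2.5 * np.eye(4)).valid


class TestPlmToTree:
    def test_three_leaf(self):
        m = np.array([[0, 2, 2], [2, 0, 2], [2, 2, 0]])
        t = plm_to_tree(m)
        assert t.n == 3

    def test_quartet_split(self, quartet_plm):
        t = plm_to_tree(quartet_plm)
        assert t.splits() == frozenset({frozenset({2, 3})})

    @pytest.mark.parametrize("n", range(3, 8))
    def test_roundtrip_identity_up_to_isomorphism(self, n):
        for t in enumerate_ubts(n):
            t2 = plm_to_tree(tree_to_plm(t))
            assert canonical_signature(t2) == canonical_signature(t)

    def test_invalid_input_rejected(self):
        m = np.full((5, 5), 4)
        np.fill_diagonal(m, 0)
        with pytest.raises(ValueError, match="not a PLM"):
            plm_to_tree(m)


class TestBmeLength:
    def test_unit_star(self):
        d = np.ones((3, 3)) - np.eye(3)
        tau = np.full((3, 3), 2)
        assert bme_length(d, tau) == pytest.approx(1.5)

    def test_zero_distances(self):
        tau = tree_to_plm(next(enumerate_ubts(5)))
        assert bme_length(np.zeros((5, 5)), tau) == 0.0

    def test_order_mismatch(self):
        with pytest.raises(ValueError, match="order mismatch"):
            bme_length(np.zeros((4, 4)), np.zeros((5, 5)))

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 10_000))
    def test_relabelling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        d = random_dm(6, seed)
        t = list(enumerate_ubts(6))[seed % 105]
        tau = tree_to_plm(t).values
        perm = rng.permutation(6)
        assert bme_length(d.values[np.ix_(perm, perm)],
                          tau[np.ix_(perm, perm)]) == \
            pytest.approx(bme_length(d, tau), rel=1e-12)


class TestGeneralizedTreeLength:
    def test_initial_star(self):
        d = random_dm(7, 0)
        star = PartialTree(7, tuple(range(7)))
        expect = d.values[np.triu_indices(7, 1)].sum() / 6
        assert generalized_tree_length(star, d) == pytest.approx(expect)

    def test_final_tree_equals_bme_length(self):
        d = random_dm(6, 1)
        # a fully agglomerated forest: three clusters
        pt = PartialTree(6, (((0, 1), 2), (3, 4), 5))
        tree = pt.to_tree()
        assert generalized_tree_length(pt, d) == \
            pytest.approx(bme_length(d, tree_to_plm(tree)), rel=1e-12)


class TestCanonicalSignature:
    def test_merge_order_invariance(self):
        a = PartialTree(6, ((0, 1), (2, 3), 4, 5))
        b = PartialTree(6, ((2, 3), (0, 1), 4, 5))
        assert canonical_signature(a) == canonical_signature(b)

    def test_quartet_topologies_distinct(self):
        sigs = {canonical_signature(t) for t in enumerate_ubts(4)}
        assert len(sigs) == 3

    def test_distinct_over_enumeration_n7(self):
        sigs = {canonical_signature(t) for t in enumerate_ubts(7)}
        assert len(sigs) == 945


class TestNewick:
    @staticmethod
    def _label_bipartitions(tree):
        all_lab = frozenset(tree.taxa)
        out = set()
        for side in tree.splits():
            lab = frozenset(tree.taxa[x] for x in side)
            out.add(frozenset({lab, all_lab - lab}))
        return frozenset(out)

    def test_roundtrip(self):
        # reader sorts taxa alphabetically, so compare label bipartitions
        taxa = ["alpha", "beta", "gamma", "delta", "eps"]
        for t in enumerate_ubts(5, taxa=taxa):
            t2 = read_newick(write_newick(t))
            assert self._label_bipartitions(t2) == self._label_bipartitions(t)
            assert t2.taxa == tuple(sorted(taxa))

    def test_rooted_representation_loads(self):
        t = read_newick("((a,b),(c,d));")
        assert t.n == 4 and t.splits() == frozenset({frozenset({2, 3})})
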