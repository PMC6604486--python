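import math

import numpy as np
import pytest

from mipfam import synthetic_data as sd
from mipfam.phylogeny import (DistanceMatrix, TreeNode, bipartitions,
                              bootstrap_supports, check_monophyly,
                              distance_from_alignment, midpoint_root, nj_tree,
                              tree_path_distances)
from mipfam.seqio import SequenceRecord


# ---------------------------------------------------------------------------
# Distances


class TestDistances:
    def test_identical_rows_are_zero(self):
        msa = [SequenceRecord("a", "MKVLH"), SequenceRecord("b", "MKVLH")]
        dm = distance_from_alignment(msa)
        assert np.allclose(dm.d, 0.0)

    def test_p_distance_arithmetic(self):
        msa = [SequenceRecord("a", "AAAAAAAAAA"), SequenceRecord("b", "AAAAAAAAWW")]
        dm = distance_from_alignment(msa)
        assert dm.d[0, 1] == pytest.approx(0.2)

    def test_poisson_closed_form(self):
        msa = [SequenceRecord("a", "AAAAAAAAAA"), SequenceRecord("b", "AAAAAAAAWW")]
        dm = distance_from_alignment(msa, model="poisson")
        assert dm.d[0, 1] == pytest.approx(-math.log(0.8))

    def test_pairwise_deletion_of_gap_columns(self):
        # the gapped column is dropped for this pair: 1 mismatch over 4
        msa = [SequenceRecord("a", "MKVLH"), SequenceRecord("b", "MKXLW")]
        dm = distance_from_alignment(msa)
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_zero_valid_columns_names_pair(self):
        msa = [SequenceRecord("a", "MX"), SequenceRecord("b", "XW")]
        with pytest.raises(ValueError, match="a.*b"):
            distance_from_alignment(msa)


def test_distance_matrix_validation():
    with pytest.raises(ValueError):
        DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError):
        DistanceMatrix(("a", "b"), np.array([[0.5, 1.0], [1.0, 0.0]]))


# ---------------------------------------------------------------------------
# Neighbor joining


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5],
                      [0.3, 0.0, 0.6],
                      [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(("a", "b", "c"), d))
        lengths = {n.name: n.branch_length for n in tree.children}
        assert lengths["a"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["b"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["c"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_additive_matrix_recovered_exactly(self):
        """On additive matrices NJ returns the generating topology and its
        branch lengths (path distances match to 1e-9)."""
        for seed in range(10):
            true_tree, dm = sd.make_random_additive_tree(5 + seed % 8, seed=seed)
            tree = nj_tree(dm)
            assert bipartitions(tree) == bipartitions(true_tree)
            back = tree_path_distances(tree).reorder(dm.labels)
            assert np.abs(back.d - dm.d).max() < 1e-9

    def test_matches_scikit_bio_topology(self):
        """Independent cross-check: scikit-bio's NJ yields the same unrooted
        topology on random non-additive matrices."""
        import skbio

        rng = np.random.default_rng(12)
        for rep in range(5):
            n = 7
            noise = rng.uniform(0.01, 1.0, size=(n, n))
            d = (noise + noise.T) / 2
            np.fill_diagonal(d, 0.0)
            labels = tuple(f"t{i}" for i in range(n))
            ours = nj_tree(DistanceMatrix(labels, d))
            sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
            sk_parts = set()
            all_leaves = frozenset(labels)
            anchor = min(all_leaves)
            for node in sk_tree.non_tips(include_self=False):
                clade = frozenset(t.name for t in node.tips())
                side = all_leaves - clade if anchor in clade else clade
                if 2 <= len(side) <= n - 2:
                    sk_parts.add(side)
            assert bipartitions(ours) == sk_parts

    def test_label_permutation_invariance(self):
        _, dm = sd.make_random_additive_tree(8, seed=42)
        perm = list(dm.labels)[::-1]
        tree_a = nj_tree(dm)
        tree_b = nj_tree(dm.reorder(perm))
        assert bipartitions(tree_a) == bipartitions(tree_b)

    def test_tie_break_is_deterministic(self):
        # equidistant taxa: every Q is tied; smallest index pair joins first
        n = 4
        d = np.ones((n, n)) - np.eye(n)
        labels = ("a", "b", "c", "d")
        t1 = nj_tree(DistanceMatrix(labels, d))
        t2 = nj_tree(DistanceMatrix(labels, d))
        assert t1.to_newick() == t2.to_newick()
        first_join = next(n_ for n_ in t1.walk()
                          if not n_.is_leaf and len(n_.leaf_names()) == 2)
        assert set(first_join.leaf_names()) == {"a", "b"}

    def test_negative_estimates_clamped_and_flagged(self):
        d = np.array([[0.0, 0.1, 0.4, 0.4],
                      [0.1, 0.0, 0.4, 0.4],
                      [0.4, 0.4, 0.0, 0.02],
                      [0.4, 0.4, 0.02, 0.0]])
        tree = nj_tree(DistanceMatrix(("a", "b", "c", "d"), d))
        assert all(n.branch_length >= 0 for n in tree.walk())


# ---------------------------------------------------------------------------
# Rooting and monophyly


class TestMonophyly:
    def _quartet(self):
        a1 = TreeNode(name="A1", branch_length=0.1)
        a2 = TreeNode(name="A2", branch_length=0.1)
        b1 = TreeNode(name="B1", branch_length=0.1)
        b2 = TreeNode(name="B2", branch_length=0.1)
        left = TreeNode(children=[a1, a2], branch_length=0.3)
        right = TreeNode(children=[b1, b2], branch_length=0.3)
        return TreeNode(children=[left, right])

    def test_clean_split_is_monophyletic(self):
        tree = self._quartet()
        result = check_monophyly(tree, {"A": ["A1", "A2"], "B": ["B1", "B2"]})
        assert result == {"A": True, "B": True}

    def test_interleaved_groups_are_not(self):
        a1 = TreeNode(name="A1", branch_length=0.1)
        b1 = TreeNode(name="B1", branch_length=0.1)
        a2 = TreeNode(name="A2", branch_length=0.1)
        b2 = TreeNode(name="B2", branch_length=0.1)
        left = TreeNode(children=[a1, b1], branch_length=0.3)
        right = TreeNode(children=[a2, b2], branch_length=0.3)
        tree = TreeNode(children=[left, right])
        result = check_monophyly(tree, {"A": ["A1", "A2"], "B": ["B1", "B2"]})
        assert result == {"A": False, "B": False}

    def test_absent_label_is_error(self):
        with pytest.raises(ValueError, match="ghost"):
            check_monophyly(self._quartet(), {"A": ["A1", "ghost"]})

    def test_midpoint_root_preserves_path_distances(self):
        tree, dm = sd.make_random_additive_tree(7, seed=9)
        rooted = midpoint_root(tree)
        back = tree_path_distances(rooted).reorder(dm.labels)
        assert np.abs(back.d - dm.d).max() < 1e-9

    def test_planted_subfamily_clades_all_monophyletic(self):
        msa, groups = sd.make_clade_msa(
            {"PIP": 7, "TIP": 6, "NIP": 6, "SIP": 5, "XIP": 6},
            length=400, seed=21)
        tree = nj_tree(distance_from_alignment(msa))
        assert all(check_monophyly(tree, groups).values())


# ---------------------------------------------------------------------------
# Bootstrap


class TestBootstrap:
    def test_zero_replicates_gives_no_supports(self):
        msa, _ = sd.make_clade_msa({"A": 3, "B": 3}, length=100, seed=2)
        tree = bootstrap_supports(msa, n_reps=0)
        assert all(n.support is None for n in tree.walk())

    def test_supports_reproducible_for_fixed_seed(self):
        msa, _ = sd.make_clade_msa({"A": 4, "B": 4}, length=150, seed=3)
        t1 = bootstrap_supports(msa, n_reps=50, seed=11)
        t2 = bootstrap_supports(msa, n_reps=50, seed=11)
        assert t1.to_newick() == t2.to_newick()

    def test_point_topology_independent_of_seed(self):
        msa, _ = sd.make_clade_msa({"A": 4, "B": 4}, length=150, seed=3)
        t1 = bootstrap_supports(msa, n_reps=20, seed=1)
        t2 = bootstrap_supports(msa, n_reps=20, seed=999)
        assert bipartitions(t1) == bipartitions(t2)

    def test_supports_bounded_0_100(self):
        msa, _ = sd.make_clade_msa({"A": 5, "B": 5}, length=120, seed=8)
        tree = bootstrap_supports(msa, n_reps=50, seed=5)
        sup = [n.support for n in tree.walk() if n.support is not None]
        assert sup and all(0 <= s <= 100 for s in sup)

    def test_planted_clades_get_high_support(self):
        """Two deeply diverged 10-leaf clades in a 20-taxon alignment are
        supported at >=90% with 200 replicates."""
        msa, groups = sd.make_clade_msa({"A": 10, "B": 10}, length=300, seed=13)
        tree = bootstrap_supports(msa, n_reps=200, seed=7)
        all_leaves = frozenset(r.id for r in msa)
        anchor = min(all_leaves)
        for members in groups.values():
            side = frozenset(members)
            canonical = all_leaves - side if anchor in side else side
            supports = [n.support for n in tree.walk()
                        if not n.is_leaf and n.support is not None
                        and _canonical_side(n, all_leaves, anchor) == canonical]
            assert supports and supports[0] >= 90


def _canonical_side(node, all_leaves, anchor):
    clade = frozenset(node.leaf_names())
    return all_leaves - clade if anchor in clade else clade
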