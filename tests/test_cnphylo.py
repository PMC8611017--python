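"""Minimum-event distances against the BFS oracle, NJ tree building,
Sankoff ancestral reconstruction and jackknife support."""

import itertools
import math

import numpy as np
import pytest

from mrevo.cnphylo import (bfs_event_distances, build_cn_tree,
                           event_distance, jackknife_support,
                           meet_ancestor_distance, profile_distance,
                           reconstruct_ancestors, tree_clades)
from mrevo.errors import InvalidInputError


class TestEventDistance:
    def test_identity(self):
        a = np.array([1, 2, 0, 3])
        assert event_distance(a, a) == 0

    def test_single_gain_spanning_two_segments(self):
        assert event_distance([1, 1, 1, 1, 1], [1, 1, 2, 2, 1]) == 1

    def test_loss_irreversibility(self):
        assert event_distance([1], [0]) == 1
        assert math.isinf(event_distance([0], [1]))

    def test_zero_segment_splits_gain(self):
        # the zero-copy segment is a barrier: two events, not one
        assert event_distance([1, 0, 1], [2, 0, 2]) == 2

    def test_chromosome_boundary_splits_event(self):
        assert event_distance([1, 1], [2, 2], chrom_index=[0, 1]) == 2
        assert event_distance([1, 1], [2, 2], chrom_index=[0, 0]) == 1

    def test_mixed_gain_and_loss(self):
        assert event_distance([1, 2], [2, 1]) == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            event_distance([1, 1], [1])

    def test_exhaustive_oracle_agreement_short_vectors(self):
        # all sources of length <= 3 with copy numbers <= 3, all targets
        for length in (1, 2, 3):
            for a in itertools.product(range(4), repeat=length):
                oracle = bfs_event_distances(a, max_cn=5)
                for b in itertools.product(range(4), repeat=length):
                    d = event_distance(np.array(a), np.array(b))
                    assert d == oracle.get(b, math.inf), (a, b)

    def test_oracle_agreement_with_chromosome_boundary(self):
        ci = np.array([0, 0, 1])
        for a in itertools.product(range(3), repeat=3):
            oracle = bfs_event_distances(a, ci, max_cn=4)
            for b in itertools.product(range(3), repeat=3):
                d = event_distance(np.array(a), np.array(b), ci)
                assert d == oracle.get(b, math.inf), (a, b)


class TestMeetAncestor:
    def test_complementary_losses_route_through_meet(self):
        a = np.array([[0, 1], [1, 1]])
        b = np.array([[1, 1], [0, 1]])
        assert math.isinf(profile_distance(a, b))
        assert meet_ancestor_distance(a, b) == 2

    def test_shared_events_cancel(self):
        # both profiles share a gain: the meet keeps it, distance counts
        # only the private differences
        base = np.ones((4, 2), dtype=int)
        base[0, 0] = 2
        a = base.copy(); a[1, 0] = 0
        b = base.copy(); b[1, 1] = 0
        assert meet_ancestor_distance(a, b) == 2


SEG_CHROMS = np.arange(20)    # one segment per chromosome: events never merge


def tetra_profiles(n_seg=20):
    """Four samples in two cherries plus shared trunk events.

    Each segment sits on its own chromosome (``SEG_CHROMS``), so every
    altered segment is one event.
    """
    base = np.ones((n_seg, 2), dtype=int)
    base[0, 0] = 2                    # trunk gain
    ab = base.copy(); ab[2, 0] = 2; ab[3, 0] = 2    # clade {a, b}
    cd = base.copy(); cd[5, 1] = 0; cd[6, 1] = 0; cd[7, 1] = 0
    a = ab.copy(); a[10, 0] = 2; a[11, 0] = 2
    b = ab.copy(); b[12, 1] = 0; b[13, 1] = 0
    c = cd.copy(); c[14, 0] = 3; c[15, 0] = 3
    d = cd.copy(); d[16, 0] = 0; d[17, 0] = 0
    return {"a": a, "b": b, "c": c, "d": d}


class TestTreeBuilding:
    def test_two_identical_profiles_zero_length_cherry(self):
        p = np.ones((5, 2), dtype=int)
        p[0, 0] = 3
        tree = build_cn_tree({"x": p, "y": p.copy()})
        assert tree.distance_matrix.loc["x", "y"] == 0

    def test_planted_cherries_recovered(self):
        tree = build_cn_tree(tetra_profiles(), SEG_CHROMS)
        assert tree.clades() == {frozenset({"a", "b"}),
                                 frozenset({"c", "d"})}

    def test_duplicate_sample_does_not_regroup_others(self):
        profiles = tetra_profiles()
        base_clades = build_cn_tree(profiles, SEG_CHROMS).clades()
        profiles["c2"] = profiles["c"].copy()
        clades = build_cn_tree(profiles, SEG_CHROMS).clades()
        stripped = {frozenset(x for x in cl if x != "c2") for cl in clades}
        stripped = {c for c in stripped if len(c) >= 2}
        assert base_clades <= stripped

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            build_cn_tree({"x": np.ones((3, 2), dtype=int)})

    def test_no_negative_branch_lengths(self):
        tree = build_cn_tree(tetra_profiles(), SEG_CHROMS)
        for node in tree.tree.postorder():
            if node.length is not None:
                assert node.length >= 0


class TestAncestors:
    def test_two_equal_leaves_mrca_is_their_profile(self):
        p = np.array([[1, 1], [1, 1], [2, 1]])
        tree = build_cn_tree({"x": p, "y": p.copy()})
        tree = reconstruct_ancestors(tree, {"x": p, "y": p.copy()})
        (anc_name, anc_prof), = [kv for kv in tree.ancestral.items()
                                 if kv[0] != "diploid"]
        assert np.array_equal(anc_prof, p)
        # the single shared gain sits on the root branch
        assert tree.branch_events[anc_name] == 1
        assert tree.branch_events["x"] == 0
        assert tree.branch_events["y"] == 0

    def test_all_diploid_leaves_reconstruct_diploid_everywhere(self):
        p = np.ones((6, 2), dtype=int)
        profiles = {s: p.copy() for s in "xyz"}
        tree = reconstruct_ancestors(build_cn_tree(profiles), profiles)
        for prof in tree.ancestral.values():
            assert np.all(prof == 1)
        assert all(v == 0 for v in tree.branch_events.values())

    def test_trunk_gain_in_ancestor_not_leaf_branches(self):
        profiles = tetra_profiles()
        tree = reconstruct_ancestors(build_cn_tree(profiles, SEG_CHROMS),
                                     profiles, SEG_CHROMS)
        # the trunk gain (segment 0) is in every leaf, so parsimony places
        # it in every non-root ancestor and no leaf branch pays for it
        ancestors = [p for n, p in tree.ancestral.items() if n != "diploid"]
        assert ancestors and all(p[0, 0] == 2 for p in ancestors)
        assert sum(tree.branch_events[n] for n in "abcd") == \
            sum(profile_distance(tree.ancestral[
                tree.tree.find(n).parent.name], profiles[n], SEG_CHROMS)
                for n in "abcd")

    def test_parsimony_bound(self):
        profiles = tetra_profiles()
        tree = reconstruct_ancestors(build_cn_tree(profiles, SEG_CHROMS),
                                     profiles, SEG_CHROMS)
        total = sum(tree.branch_events.values())
        independent = sum(
            profile_distance(np.ones_like(p), p, SEG_CHROMS)
            for p in profiles.values())
        assert total <= independent

    def test_sankoff_matches_exhaustive_labelling_on_tiny_instance(self):
        # one internal ancestor, one segment: enumerate all its states
        profiles = {"x": np.array([[2, 1]]), "y": np.array([[3, 1]])}
        tree = reconstruct_ancestors(build_cn_tree(profiles), profiles)
        total = sum(tree.branch_events.values())
        best = min(abs(1 - s) + abs(s - 2) + abs(s - 3)
                   for s in range(0, 6) if s > 0)
        assert total == best


class TestJackknife:
    def test_identical_cherry_supported_at_100(self):
        rng = np.random.default_rng(0)
        p = np.ones((30, 2), dtype=int)
        a = p.copy(); a[:10, 0] = 2
        profiles = {"x": a, "y": a.copy(),
                    "z": p.copy(), "w": p.copy()}
        support = jackknife_support(profiles, np.arange(30),
                                    n_replicates=50, seed=0)
        assert support[frozenset({"x", "y"})] == 100.0

    def test_support_bounded(self):
        profiles = tetra_profiles()
        support = jackknife_support(profiles, SEG_CHROMS, n_replicates=30, seed=1)
        assert all(0.0 <= v <= 100.0 for v in support.values())

    def test_deterministic_given_seed(self):
        profiles = tetra_profiles()
        s1 = jackknife_support(profiles, SEG_CHROMS, n_replicates=20, seed=5)
        s2 = jackknife_support(profiles, SEG_CHROMS, n_replicates=20, seed=5)
        assert s1 == s2

    def test_needs_three_samples(self):
        p = np.ones((5, 2), dtype=int)
        with pytest.raises(InvalidInputError):
            jackknife_support({"x": p, "y": p.copy()})
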