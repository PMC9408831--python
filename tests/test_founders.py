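"""Founder detection, the f-criterion, and cluster construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import founderscan as fs
from founderscan.founders import source_derived_branches
from founderscan.tree_io import TreeError

from conftest import brute_force_founder_map, make_tree, random_small_tree


class TestFindFounderNodes:
    def test_zero_path_source_marks_cherry_parent(self):
        # S1 sits at 0 mutations from the (S1,K1) parent: haplotype sampled
        ptree = make_tree("((S1:0,K1:1)A:2,S2:3)R;")
        cands = {c.node_id: c for c in fs.find_founder_nodes(ptree)}
        assert set(cands) == {"A"}
        assert cands["A"].sink_leaves == ("K1",)
        assert cands["A"].source_match == "sampled"

    def test_root_founder_via_zero_path(self):
        ptree = make_tree("((K1:1,K2:0)A:1,S1:0)R;")
        cands = {c.node_id: c for c in fs.find_founder_nodes(ptree)}
        assert set(cands) == {"R"}
        assert cands["R"].sink_leaves == ("K1", "K2")

    def test_every_sink_leaf_maps_to_one_candidate(self):
        ptree = make_tree("((S1:0,K1:1)A:2,(K2:1,K3:0)B:1,S2:3)R;")
        cands = fs.find_founder_nodes(ptree)
        seen = [s for c in cands for s in c.sink_leaves]
        assert sorted(seen) == ["K1", "K2", "K3"]
        assert len(seen) == len(set(seen))

    def test_requires_role_annotation(self):
        ptree = make_tree("(S1:0,K1:1);", annotate=False)
        with pytest.raises(TreeError, match="annotated"):
            fs.find_founder_nodes(ptree)


class TestFCriterion:
    def test_derived_source_leaf_passes_f1(self):
        # source leaves at path counts {0, 1} from the founder node
        ptree = make_tree("(S1:0,S2:1,K1:2)R;")
        (cand,) = fs.find_founder_nodes(ptree)
        assert cand.source_derived_branches >= 1
        assert fs.apply_f_criterion(cand, 1)

    def test_lone_zero_path_source_fails_f1_passes_f0(self):
        ptree = make_tree("(S1:0,K1:2)R;")
        (cand,) = fs.find_founder_nodes(ptree)
        assert not fs.apply_f_criterion(cand, 1)
        assert fs.apply_f_criterion(cand, 0)

    def test_f0_accepts_everything(self):
        ptree = make_tree("((S1:0,K1:1)A:2,S2:3)R;")
        for cand in fs.find_founder_nodes(ptree):
            assert fs.apply_f_criterion(cand, 0)

    def test_negative_f_fatal(self):
        ptree = make_tree("(S1:0,K1:2)R;")
        (cand,) = fs.find_founder_nodes(ptree)
        with pytest.raises(ValueError, match="non-negative"):
            fs.apply_f_criterion(cand, -1)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_passing_set_monotone_in_f(self, seed):
        ptree = random_small_tree(np.random.default_rng(seed))
        cands = fs.find_founder_nodes(ptree)
        for k in range(3):
            passing_next = {
                c.node_id for c in cands if fs.apply_f_criterion(c, k + 1)
            }
            passing = {
                c.node_id for c in cands if fs.apply_f_criterion(c, k)
            }
            assert passing_next <= passing


class TestBuildClusters:
    def test_shared_founder_groups_leaves(self):
        ptree = make_tree("((K1:1,K2:0)A:1,S1:0,S2:2)R;")
        cands = fs.find_founder_nodes(ptree)
        (cluster,) = fs.build_clusters(ptree, cands, f=1)
        assert cluster.n == 2
        assert cluster.node_id == "R"

    def test_failed_inner_founder_reassigned_outward(self):
        # inner node A is attested via its zero-path source leaf S1 but
        # shows no derived source branch; K1, K2 move rootward to R
        ptree = make_tree("((K1:1,K2:2,S1:0)A:1,(S2:0,S3:2)B:0)R;")
        cands = {c.node_id for c in fs.find_founder_nodes(ptree)}
        assert cands == {"A"}
        (cluster,) = fs.build_clusters(
            ptree, fs.find_founder_nodes(ptree), f=1
        )
        assert cluster.node_id == "R"
        assert cluster.path_counts == {"K1": 2, "K2": 3}

    def test_star_conservation_identity(self, star_cluster):
        assert sorted(star_cluster.path_counts.values()) == [0, 1, 2, 3]
        direct = sum(star_cluster.path_counts.values())
        via_branches = sum(b.n_b * b.m_b for b in star_cluster.branches)
        assert direct == via_branches == 6

    def test_all_dropped_warns_returns_empty(self):
        ptree = make_tree("(S1:0,K1:2)R;")
        cands = fs.find_founder_nodes(ptree)
        with pytest.warns(UserWarning, match="dropped"):
            clusters = fs.build_clusters(ptree, cands, f=99)
        assert clusters == []

    def test_empty_candidate_list_fatal(self):
        ptree = make_tree("(S1:0,K1:2)R;")
        with pytest.raises(TreeError, match="candidates"):
            fs.build_clusters(ptree, [], f=0)


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 100_000))
def test_founder_assignment_matches_brute_force(seed):
    """Oracle equivalence on random trees of <= 12 leaves.

    The oracle enumerates every (sink leaf, ancestor) pair and applies
    the attestation rule from first principles.
    """
    ptree = random_small_tree(np.random.default_rng(seed))
    expected = brute_force_founder_map(ptree)
    got = {
        s: c.node_id
        for c in fs.find_founder_nodes(ptree)
        for s in c.sink_leaves
    }
    for sid, founder in expected.items():
        assert got.get(sid) == founder, f"sink leaf {sid}"


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 100_000))
def test_f0_clusters_partition_attested_sink_leaves(seed):
    """Under f=0 every attested sink leaf lands in exactly one cluster."""
    ptree = random_small_tree(np.random.default_rng(seed))
    cands = fs.find_founder_nodes(ptree)
    if not cands:
        return
    clusters = fs.build_clusters(ptree, cands, f=0)
    assigned = [s for c in clusters for s in c.sink_leaves]
    assert len(assigned) == len(set(assigned))
    with_founder = [
        s for s, nid in brute_force_founder_map(ptree).items()
        if nid is not None
    ]
    assert sorted(assigned) == sorted(with_founder)


def test_source_derived_branches_counts_mutated_source_children():
    ptree = make_tree("(S1:0,S2:1,S3:2,K1:1)R;")
    assert source_derived_branches(ptree.root) == 2
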