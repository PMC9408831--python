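"""Source-region attribution and epoch-resolved composition tables."""

import numpy as np
import pandas as pd
import pytest

import founderscan as fs
from founderscan.epochs import EpochAllocation, EpochModel
from founderscan.geography import epoch_region_composition

from conftest import SNK, make_tree, meta_for


def tree_with_regions(newick, regions_by_sample):
    names = list(regions_by_sample)
    ptree = fs.parse_tree(
        newick, meta_for(names, [regions_by_sample[s] for s in names])
    )
    source = {r for r in regions_by_sample.values() if r != SNK}
    fs.annotate_roles(ptree, fs.RoleAssignment(source, {SNK}))
    return ptree


class TestAttribution:
    def test_majority_vote(self):
        ptree = tree_with_regions(
            "(S1:0,S2:1,S3:1,K1:1)R;",
            {"S1": "West", "S2": "West", "S3": "Eastern", "K1": SNK},
        )
        _, clusters = fs.identify_founders(ptree, f=1)
        attr = fs.infer_source_region(clusters[0], ptree)
        assert attr.region == "West"
        assert attr.support == pytest.approx(2 / 3)
        assert not attr.ambiguous

    def test_pure_distance_tie_break(self):
        ptree = tree_with_regions(
            "(S1:1,S2:3,K1:1)R;",
            {"S1": "West", "S2": "Eastern", "K1": SNK},
        )
        _, clusters = fs.identify_founders(ptree, f=1)
        attr = fs.infer_source_region(clusters[0], ptree)
        assert attr.region == "West"
        assert not attr.ambiguous

    def test_persistent_tie_lexicographic_and_flagged(self):
        ptree = tree_with_regions(
            "(S1:2,S2:2,K1:1)R;",
            {"S1": "West", "S2": "Eastern", "K1": SNK},
        )
        _, clusters = fs.identify_founders(ptree, f=1)
        attr = fs.infer_source_region(clusters[0], ptree)
        assert attr.region == "Eastern"
        assert attr.ambiguous

    def test_fallback_to_rootward_ancestor(self):
        # A carries the founder haplotype only through a zero-mutation
        # path up to S1, so the cluster node has no source descendants;
        # the region vote must fall back to the nearest rootward node
        ptree = tree_with_regions(
            "((K1:1,K2:0)A:0,S1:0,S2:1)R;",
            {"K1": SNK, "K2": SNK, "S1": "Central", "S2": "Central"},
        )
        _, clusters = fs.identify_founders(ptree, f=0)
        (cluster,) = [c for c in clusters if c.node_id == "A"]
        attr = fs.infer_source_region(cluster, ptree)
        assert attr.region == "Central"


def alloc(labels, posteriors_by_founder):
    model = EpochModel(times=(8000.0, 500.0), labels=labels)
    posts = {k: np.array(v) for k, v in posteriors_by_founder.items()}
    weighted = [(1, p) for p in posts.values()]
    total = sum(p for _, p in weighted)
    return EpochAllocation(
        epochs=model, posteriors=posts, proportions=total / total.sum()
    )


def fake_cluster(founder_id, node_id, sink_ids):
    from founderscan.founders import ClusterBranch, FounderCluster

    return FounderCluster(
        founder_id=founder_id,
        node_id=node_id,
        path_counts={s: 1 for s in sink_ids},
        branches=tuple(
            ClusterBranch(node_id=s, n_b=1, m_b=1) for s in sink_ids
        ),
    )


class TestComposition:
    def test_disjoint_founders_identity_matrix(self):
        labels = ("prehistoric", "historical")
        clusters = [fake_cluster("F1", "N1", ["a"]),
                    fake_cluster("F2", "N2", ["b"])]
        attributions = {
            "F1": fs.RegionAttribution("F1", "Eastern", 1.0, False),
            "F2": fs.RegionAttribution("F2", "West", 1.0, False),
        }
        allocation = alloc(labels, {"F1": [1.0, 0.0], "F2": [0.0, 1.0]})
        mat = epoch_region_composition(attributions, allocation, clusters)
        assert mat.loc["Eastern", "prehistoric"] == 1.0
        assert mat.loc["West", "historical"] == 1.0
        assert mat.loc["Eastern", "historical"] == 0.0

    def test_single_region_rows_of_ones(self):
        labels = ("prehistoric", "historical")
        clusters = [fake_cluster("F1", "N1", ["a"]),
                    fake_cluster("F2", "N2", ["b"])]
        attributions = {
            "F1": fs.RegionAttribution("F1", "West", 1.0, False),
            "F2": fs.RegionAttribution("F2", "West", 1.0, False),
        }
        allocation = alloc(labels, {"F1": [0.6, 0.4], "F2": [0.2, 0.8]})
        mat = epoch_region_composition(attributions, allocation, clusters)
        assert np.allclose(mat.loc["West"], 1.0)

    def test_weighted_tally_and_column_stochastic(self):
        labels = ("prehistoric", "historical")
        clusters = [fake_cluster("F1", "N1", ["a", "b", "c"]),
                    fake_cluster("F2", "N2", ["d"])]
        attributions = {
            "F1": fs.RegionAttribution("F1", "West", 1.0, False),
            "F2": fs.RegionAttribution("F2", "Eastern", 1.0, False),
        }
        allocation = alloc(labels, {"F1": [1.0, 0.0], "F2": [1.0, 0.0]})
        mat = epoch_region_composition(attributions, allocation, clusters)
        assert mat.loc["West", "prehistoric"] == pytest.approx(0.75)
        assert mat.loc["Eastern", "prehistoric"] == pytest.approx(0.25)
        assert mat["prehistoric"].sum() == pytest.approx(1.0, abs=1e-9)


class TestPopulationFrequency:
    def metadata(self):
        rows = [(f"K{i}", SNK, "coastal") for i in range(10)]
        rows += [(f"J{i}", SNK, "inland") for i in range(8)]
        rows += [("S1", "West", "west_pop")]
        return pd.DataFrame(rows,
                            columns=["sample_id", "region", "population"])

    def test_fully_allocated_fraction(self):
        meta = self.metadata()
        clusters = [fake_cluster("F1", "N1", ["K0", "K1"])]
        allocation = alloc(("prehistoric", "historical"),
                           {"F1": [1.0, 0.0]})
        freq = fs.population_epoch_frequency(meta, clusters, allocation)
        assert freq.loc["coastal", "prehistoric"] == pytest.approx(0.2)
        assert freq.loc["coastal", "not_analysed"] == pytest.approx(0.8)

    def test_population_without_clusters_all_zero(self):
        meta = self.metadata()
        clusters = [fake_cluster("F1", "N1", ["K0"])]
        allocation = alloc(("prehistoric", "historical"),
                           {"F1": [1.0, 0.0]})
        freq = fs.population_epoch_frequency(meta, clusters, allocation)
        assert freq.loc["inland", "prehistoric"] == 0.0
        assert freq.loc["inland", "historical"] == 0.0

    def test_split_posterior_splits_frequency(self):
        meta = self.metadata()
        clusters = [fake_cluster("F1", "N1", ["J0", "J1", "J2", "J3"])]
        allocation = alloc(("prehistoric", "historical"),
                           {"F1": [0.5, 0.5]})
        freq = fs.population_epoch_frequency(meta, clusters, allocation)
        assert freq.loc["inland", "prehistoric"] == pytest.approx(0.25)
        assert freq.loc["inland", "historical"] == pytest.approx(0.25)

    def test_rows_sum_to_one(self):
        meta = self.metadata()
        clusters = [fake_cluster("F1", "N1", ["K0", "J0"])]
        allocation = alloc(("prehistoric", "historical"),
                           {"F1": [0.3, 0.7]})
        freq = fs.population_epoch_frequency(meta, clusters, allocation)
        sums = freq[["prehistoric", "historical", "not_analysed"]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_unknown_population_fatal(self):
        meta = self.metadata()
        clusters = [fake_cluster("F1", "N1", ["K0"])]
        allocation = alloc(("prehistoric", "historical"),
                           {"F1": [1.0, 0.0]})
        with pytest.raises(Exception, match="absent"):
            fs.population_epoch_frequency(
                meta, clusters, allocation, populations=["atlantis"]
            )
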