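"""Geographic source attribution and epoch-resolved composition tables.

Each founder cluster is attributed to a broad source region (the
standard African scheme distinguishes North, West, Central, Eastern and
Southern Africa) by majority vote among the source leaves descending
from the founder node; ties are broken by the smaller mean tree-path
mutation distance to the founder node, and persistent ties fall back to
the lexicographically first region with an ``ambiguous`` flag. When the
founder node itself has no source-leaf descendants (possible after
f-criterion re-assignment), the vote falls back to the nearest rootward
ancestor that has some.

Two summary tables follow: the region-by-epoch composition of allocated
lineages (each epoch column sums to 1), and per-population epoch
frequencies relative to the population's *total* sample count, so the
epoch frequencies plus the non-analysed remainder sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .epochs import EpochAllocation
from .founders import FounderCluster
from .tree_io import PhyloTree, TreeError


@dataclass(frozen=True)
class RegionAttribution:
    founder_id: str
    region: str
    support: float       # fraction of qualifying source leaves in the winner
    ambiguous: bool


def _source_leaves_below(ptree: PhyloTree, node) -> list:
    out = []
    stack = [node]
    while stack:
        nd = stack.pop()
        if nd.is_leaf():
            if nd.role == "source":
                out.append(nd)
        else:
            stack.extend(nd.child_nodes())
    return out


def _path_mutations(ptree: PhyloTree, ancestor, leaf) -> int:
    total = 0
    nd = leaf
    while nd is not ancestor:
        total += nd.mutations
        nd = nd.parent_node
    return total


def infer_source_region(
    cluster: FounderCluster, ptree: PhyloTree
) -> RegionAttribution:
    """Majority region among qualifying source leaves, with tie-breaks."""
    founder = ptree.node(cluster.node_id)
    anchor = founder
    leaves = _source_leaves_below(ptree, anchor)
    while not leaves and anchor.parent_node is not None:
        anchor = anchor.parent_node
        leaves = _source_leaves_below(ptree, anchor)
    if not leaves:
        return RegionAttribution(
            founder_id=cluster.founder_id,
            region="unknown",
            support=0.0,
            ambiguous=False,
        )
    counts: dict[str, int] = {}
    dists: dict[str, list[int]] = {}
    for leaf in leaves:
        counts[leaf.region] = counts.get(leaf.region, 0) + 1
        dists.setdefault(leaf.region, []).append(
            _path_mutations(ptree, anchor, leaf)
        )
    best = max(counts.values())
    tied = sorted(r for r, c in counts.items() if c == best)
    ambiguous = False
    if len(tied) > 1:
        mean_d = {r: sum(dists[r]) / len(dists[r]) for r in tied}
        closest = min(mean_d.values())
        tied = sorted(r for r in tied if mean_d[r] == closest)
        if len(tied) > 1:
            ambiguous = True
    winner = tied[0]
    return RegionAttribution(
        founder_id=cluster.founder_id,
        region=winner,
        support=counts[winner] / len(leaves),
        ambiguous=ambiguous,
    )


def attribute_clusters(
    clusters: list[FounderCluster], ptree: PhyloTree
) -> dict[str, RegionAttribution]:
    return {c.founder_id: infer_source_region(c, ptree) for c in clusters}


def epoch_region_composition(
    attributions: dict[str, RegionAttribution],
    allocation: EpochAllocation,
    clusters: list[FounderCluster],
) -> pd.DataFrame:
    """Region x epoch matrix of lineage shares; each epoch column sums to 1."""
    labels = allocation.epochs.labels
    regions = sorted({a.region for a in attributions.values()})
    mat = pd.DataFrame(0.0, index=regions, columns=list(labels))
    for c in clusters:
        region = attributions[c.founder_id].region
        post = allocation.posteriors[c.founder_id]
        mat.loc[region] += c.n * post
    col_sums = mat.sum(axis=0)
    nonzero = col_sums > 0
    mat.loc[:, nonzero] = mat.loc[:, nonzero] / col_sums[nonzero]
    return mat


def population_epoch_frequency(
    metadata: pd.DataFrame,
    clusters: list[FounderCluster],
    allocation: EpochAllocation,
    populations: list[str] | None = None,
) -> pd.DataFrame:
    """Per-population frequency of lineages allocated to each epoch.

    Frequencies are relative to the population's total sample count in
    the metadata (analysed or not), so each row's epoch columns plus
    ``not_analysed`` sum to 1.
    """
    pop_of = dict(zip(metadata["sample_id"], metadata["population"]))
    totals = metadata["population"].value_counts().to_dict()
    if populations is None:
        populations = sorted(totals)
    else:
        missing = [p for p in populations if p not in totals]
        if missing:
            raise TreeError(f"populations absent from metadata: {missing}")
    labels = list(allocation.epochs.labels)
    freq = pd.DataFrame(0.0, index=list(populations), columns=labels)
    for c in clusters:
        post = allocation.posteriors[c.founder_id]
        for sid in c.sink_leaves:
            pop = pop_of[sid]
            if pop in freq.index:
                freq.loc[pop] += post / totals[pop]
    freq["not_analysed"] = 1.0 - freq[labels].sum(axis=1)
    freq.insert(0, "n_samples", [totals[p] for p in freq.index])
    freq.index.name = "population"
    return freq
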