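"""Shared fixtures: tiny hand-built trees and a random small-tree factory.

Naming convention for hand-built trees: sample ids starting with ``S``
are source, ``K`` sink, ``U`` unassigned; regions default to the sample
prefix so a single RoleAssignment covers every fixture.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import founderscan as fs

SRC, SNK = "Src", "Snk"
ROLES = fs.RoleAssignment({SRC}, {SNK})


def meta_for(sample_ids, regions=None, populations=None) -> pd.DataFrame:
    if regions is None:
        regions = [
            SRC if s.startswith("S") else SNK if s.startswith("K") else "Other"
            for s in sample_ids
        ]
    if populations is None:
        populations = [f"pop_{r}" for r in regions]
    return pd.DataFrame(
        {"sample_id": list(sample_ids), "region": regions,
         "population": populations}
    )


def leaf_names(newick: str) -> list[str]:
    # leaf labels sit right after "(" or ","; internal labels after ")"
    import re

    return re.findall(r"[(,]\s*([A-Za-z_]\w*)\s*:", newick)


def make_tree(newick: str, regions=None, annotate: bool = True,
              roles: fs.RoleAssignment = ROLES) -> fs.PhyloTree:
    """Parse a hand-written Newick with prefix-derived roles."""
    names = leaf_names(newick)
    ptree = fs.parse_tree(newick, meta_for(names, regions))
    if annotate:
        fs.annotate_roles(ptree, roles)
    return ptree


def random_small_tree(rng: np.random.Generator, max_leaves: int = 12):
    """A random multifurcating tree with 0–3 mutation branches.

    Leaves are randomly assigned source/sink (at least one of each);
    returns an annotated PhyloTree.
    """
    n_leaves = int(rng.integers(2, max_leaves + 1))
    roles = None
    while roles is None or len(set(roles)) < 2:
        roles = [("S", "K")[int(rng.integers(2))] for _ in range(n_leaves)]
    labels = [f"{r}{i:02d}" for i, r in enumerate(roles)]

    def build(items) -> str:
        if len(items) == 1:
            return items[0]
        k = int(rng.integers(2, min(3, len(items)) + 1))
        cuts = sorted(
            rng.choice(np.arange(1, len(items)), size=k - 1, replace=False)
        )
        parts, prev = [], 0
        for c in list(cuts) + [len(items)]:
            parts.append(items[prev:int(c)])
            prev = int(c)
        subs = [
            f"{build(p)}:{int(rng.integers(0, 4))}" for p in parts
        ]
        return "(" + ",".join(subs) + ")"

    newick = build(labels)
    if not newick.startswith("("):
        newick = f"({newick}:{int(rng.integers(0, 4))})"
    return make_tree(newick + ";")


def brute_force_founder_map(ptree: fs.PhyloTree) -> dict[str, str | None]:
    """Independent founder oracle: enumerate every (leaf, ancestor) pair.

    Attestation is evaluated directly from first principles — general
    tree-path mutation sums for the sampled-haplotype arm, and a direct
    descendant sweep for the inferred-ancestor arm — with no reuse of
    the package's component or tally machinery.
    """

    def root_path(nd):
        out = []
        while nd is not None:
            out.append(nd)
            nd = nd.parent_node
        return out

    def path_mutations(a, b) -> int:
        pa, pb = root_path(a), root_path(b)
        index_a = {id(x): i for i, x in enumerate(pa)}
        for j, x in enumerate(pb):
            if id(x) in index_a:
                i = index_a[id(x)]
                break
        return sum(n.mutations for n in pa[:i]) + sum(
            n.mutations for n in pb[:j]
        )

    def leaf_descendants(nd):
        out, stack = [], [nd]
        while stack:
            x = stack.pop()
            if x.is_leaf():
                out.append(x)
            else:
                stack.extend(x.child_nodes())
        return out

    source_leaves = [l for l in ptree.leaves() if l.role == "source"]

    def attested(nd) -> bool:
        if any(path_mutations(nd, s) == 0 for s in source_leaves):
            return True
        return not nd.is_leaf() and any(
            l.role == "source" for l in leaf_descendants(nd)
        )

    mapping: dict[str, str | None] = {}
    for leaf in ptree.leaves():
        if leaf.role != "sink":
            continue
        found = None
        anc = leaf.parent_node
        while anc is not None:
            if attested(anc):
                found = anc
                break
            anc = anc.parent_node
        mapping[leaf.sample_id] = found.node_id if found else None
    return mapping


@pytest.fixture
def star_cluster():
    """Star founder: sink path counts {0,1,2,3}, one derived source branch."""
    ptree = make_tree("(S1:0,S2:1,K1:0,K2:1,K3:2,K4:3)R;")
    _, clusters = fs.identify_founders(ptree, f=1)
    assert len(clusters) == 1
    return clusters[0]
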