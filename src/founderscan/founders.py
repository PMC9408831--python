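"""Founder detection: shared source/sink haplotypes and the f-criterion.

A *founder node* is the most recent ancestor of a sink lineage whose
haplotype is attested in the source population. Attestation has two
arms:

1. **Sampled haplotype** — some source leaf is reachable from the node
   through a path of total mutation count zero (the identical haplotype
   was sampled in the source). Zero-mutation paths may ascend as well as
   descend, so this is computed on connected components of zero-length
   branches.
2. **Inferred ancestral haplotype** — the node is an internal (inferred)
   node with at least one source-leaf descendant.

Each sink leaf maps to its nearest attested proper ancestor, or to "no
founder" when none exists. Candidates are then screened with the
*f-criterion*: a founder match must display derived diversity in the
source, operationalised as at least ``f`` child branches of the founder
node that lead to source leaves and carry >= 1 mutation (``f=1`` is the
classical f1 rule; ``f=0`` accepts any attested match). Sink leaves
whose nearest attested ancestor fails the criterion are re-assigned to
the next attested ancestor rootward that passes, or dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy

from .tree_io import PhyloTree, TreeError


@dataclass(frozen=True)
class FounderCandidate:
    """A potential founder node and the sink leaves it would explain."""

    node_id: str
    sink_leaves: tuple[str, ...]
    source_match: str          # "sampled" (zero-path leaf) or "ancestral"
    source_derived_branches: int

    def __post_init__(self):
        if not self.sink_leaves:
            raise ValueError("candidate with no sink leaves")


@dataclass(frozen=True)
class ClusterBranch:
    """One branch of a cluster's sink-restricted subtree."""

    node_id: str   # node the branch leads into
    n_b: int       # cluster sink leaves below the branch
    m_b: int       # mutations on the branch


@dataclass(frozen=True)
class FounderCluster:
    """A screened founder node plus its assigned sink descendants.

    ``path_counts`` maps each assigned sink sample to the total mutation
    count on its path down from the founder node (the branch *into* the
    founder is excluded; it predates the founder event). ``branches``
    is the sink-restricted subtree spanning the assigned leaves, the
    input to the Saillard variance estimator. The conservation identity
    ``sum(path_counts) == sum(n_b * m_b)`` holds by construction.
    """

    founder_id: str
    node_id: str
    path_counts: dict[str, int]
    branches: tuple[ClusterBranch, ...]

    @property
    def n(self) -> int:
        return len(self.path_counts)

    @property
    def sink_leaves(self) -> tuple[str, ...]:
        return tuple(self.path_counts)

    @property
    def total_mutations(self) -> int:
        return sum(self.path_counts.values())


def _zero_attested(ptree: PhyloTree) -> dict[int, bool]:
    """Per node (by id()): does its zero-mutation component hold a source leaf?

    Contract every zero-length branch; a node is zero-attested iff its
    component contains a sampled source haplotype.
    """
    comp_of: dict[int, int] = {}
    has_source: dict[int, bool] = {}
    next_comp = 0
    for nd in ptree.nodes():
        if nd.parent_node is None or nd.mutations > 0:
            comp = next_comp
            next_comp += 1
            has_source[comp] = False
        else:
            comp = comp_of[id(nd.parent_node)]
        comp_of[id(nd)] = comp
        if nd.is_leaf() and nd.role == "source":
            has_source[comp] = True
    return {nid: has_source[comp] for nid, comp in comp_of.items()}


def _is_attested(nd: dendropy.Node, zero_ok: dict[int, bool]) -> str | None:
    if zero_ok[id(nd)]:
        return "sampled"
    if not nd.is_leaf() and nd.n_source >= 1:
        return "ancestral"
    return None


def source_derived_branches(nd: dendropy.Node) -> int:
    """Child branches of ``nd`` leading to source leaves with >= 1 mutation."""
    return sum(
        1 for c in nd.child_nodes() if c.n_source >= 1 and c.mutations >= 1
    )


def find_founder_nodes(ptree: PhyloTree) -> list[FounderCandidate]:
    """Map every sink leaf to its nearest source-attested proper ancestor.

    Returns the distinct founder nodes with their sink leaf sets, in
    tree preorder. Sink leaves with no attested ancestor are omitted
    (no founder detectable).
    """
    if ptree.roles is None:
        raise TreeError("tree must be role-annotated before founder search")
    zero_ok = _zero_attested(ptree)
    by_node: dict[str, list[str]] = {}
    match_kind: dict[str, str] = {}
    for leaf in ptree.leaves():
        if leaf.role != "sink":
            continue
        for anc in ptree.ancestors(leaf):
            kind = _is_attested(anc, zero_ok)
            if kind is not None:
                by_node.setdefault(anc.node_id, []).append(leaf.sample_id)
                match_kind[anc.node_id] = kind
                break
    out = []
    for nd in ptree.nodes():
        if nd.node_id in by_node:
            out.append(
                FounderCandidate(
                    node_id=nd.node_id,
                    sink_leaves=tuple(sorted(by_node[nd.node_id])),
                    source_match=match_kind[nd.node_id],
                    source_derived_branches=source_derived_branches(nd),
                )
            )
    return out


def apply_f_criterion(candidate: FounderCandidate, f: int) -> bool:
    """``f`` derived source lineages required at the founder node.

    ``f=1`` encodes the f1 criterion (some diversity in the source);
    ``f=0`` accepts any source-attested match.
    """
    if f < 0:
        raise ValueError(f"f must be a non-negative integer, got {f}")
    return candidate.source_derived_branches >= f


def _cluster_from_leaves(
    ptree: PhyloTree, founder: dendropy.Node, leaf_ids: list[str],
    founder_id: str,
) -> FounderCluster:
    """Build path counts and the sink-restricted subtree for one cluster."""
    path_counts: dict[str, int] = {}
    n_below: dict[str, int] = {}   # node_id of branch endpoint -> n_b
    m_of: dict[str, int] = {}
    order: list[str] = []
    for sid in sorted(leaf_ids):
        leaf = ptree.node(sid)
        total = 0
        chain = []
        nd = leaf
        while nd is not founder:
            chain.append(nd)
            total += nd.mutations
            nd = nd.parent_node
        path_counts[sid] = total
        for nd in chain:
            if nd.node_id not in n_below:
                n_below[nd.node_id] = 0
                m_of[nd.node_id] = nd.mutations
                order.append(nd.node_id)
            n_below[nd.node_id] += 1
    branches = tuple(
        ClusterBranch(node_id=b, n_b=n_below[b], m_b=m_of[b]) for b in order
    )
    return FounderCluster(
        founder_id=founder_id,
        node_id=founder.node_id,
        path_counts=path_counts,
        branches=branches,
    )


def build_clusters(
    ptree: PhyloTree,
    candidates: list[FounderCandidate],
    f: int = 1,
) -> list[FounderCluster]:
    """Screen candidates with the f-criterion and group sink leaves.

    Sink leaves whose nearest attested ancestor fails the criterion are
    re-assigned to the next attested ancestor rootward that passes it;
    leaves with no passing ancestor are dropped (warning, not fatal).
    Clusters are numbered ``F001, F002, ...`` in tree preorder.
    """
    if not candidates:
        raise TreeError("no founder candidates to cluster")
    if f < 0:
        raise ValueError(f"f must be a non-negative integer, got {f}")
    zero_ok = _zero_attested(ptree)

    assignment: dict[str, list[str]] = {}
    n_dropped = 0
    for cand in candidates:
        for sid in cand.sink_leaves:
            leaf = ptree.node(sid)
            chosen = None
            for anc in ptree.ancestors(leaf):
                if _is_attested(anc, zero_ok) is None:
                    continue
                if source_derived_branches(anc) >= f:
                    chosen = anc
                    break
            if chosen is None:
                n_dropped += 1
            else:
                assignment.setdefault(chosen.node_id, []).append(sid)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} sink leaf/leaves had no founder node passing "
            f"f={f} and were dropped",
            stacklevel=2,
        )
    clusters = []
    idx = 0
    for nd in ptree.nodes():
        if nd.node_id in assignment:
            idx += 1
            clusters.append(
                _cluster_from_leaves(
                    ptree, nd, assignment[nd.node_id], f"F{idx:03d}"
                )
            )
    return clusters


def identify_founders(
    ptree: PhyloTree, f: int = 1
) -> tuple[list[FounderCandidate], list[FounderCluster]]:
    """Full founder search: candidates plus f-screened clusters."""
    candidates = find_founder_nodes(ptree)
    if not candidates:
        return [], []
    clusters = build_clusters(ptree, candidates, f=f)
    return candidates, clusters
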