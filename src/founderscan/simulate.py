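"""Synthetic source/sink phylogenies with known founder events.

The generator emulates the data structure that founder analysis
consumes: a source population tree in which designated founder nodes
each seed a sink subtree, with mutation counts drawn Poisson from
branch durations under the linear molecular clock (1 substitution per
2565 years by default). Ground truth — the founder nodes, their event
times and source regions, and their sink samples — is recorded so every
pipeline stage can be tested by parameter recovery.

Construction guarantees, per designated founder node:

* at least one source leaf at zero mutations from it (the founder
  haplotype is *sampled* in the source), and
* at least one derived source branch (>= 1 mutation), so the f1
  criterion passes by construction.

Sink subtrees are stars by default — per-leaf mutation counts are then
i.i.d. Poisson(T / years_per_mutation), making rho and the Saillard
error analytically checkable — or a "cherry-star" mix that exercises
the general branch-weighted variance formula.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import dendropy
import numpy as np
import pandas as pd

from . import tree_io
from .tree_io import PhyloTree

SOURCE_REGIONS = (
    "North Africa",
    "West Africa",
    "Central Africa",
    "Eastern Africa",
    "Southern Africa",
)

#: Default sink-side region label for simulated datasets.
SINK_REGION = "Sink"


@dataclass(frozen=True)
class EpochSpec:
    """One planned migration event: when, how many founders, from where."""

    time_years: float
    n_founders: int
    sink_per_founder: int
    source_region: str

    def __post_init__(self):
        if not 0 <= self.time_years <= 25000:
            raise ValueError("epoch time must lie within [0, 25000] years")
        if self.n_founders <= 0 or self.sink_per_founder <= 0:
            raise ValueError("founder and sink counts must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults: a 75:25 historical/prehistoric split.

    30 founders arrive at 500 y from West Africa and 10 at 8000 y from
    Eastern Africa, 10 sink samples each — twin migration pulses with
    sample-weighted proportions 75:25. Each founder clade carries three
    source leaves (one identical to the founder haplotype, two derived);
    background source cherries add unrelated source diversity.
    """

    seed: int = 0
    years_per_mutation: float = 2565.0
    epochs: tuple[EpochSpec, ...] = (
        EpochSpec(500.0, 30, 10, "West Africa"),
        EpochSpec(8000.0, 10, 10, "Eastern Africa"),
    )
    source_leaves_per_founder: int = 3
    n_background_clades: int = 10
    source_clade_depth_years: float = 5000.0
    join_branch_years: float = 2000.0
    sink_shape: str = "star"          # "star" or "cherry-star"
    sink_region: str = SINK_REGION
    sink_populations: tuple[str, ...] = ("diaspora",)

    def __post_init__(self):
        if self.years_per_mutation <= 0:
            raise ValueError("years_per_mutation must be positive")
        if self.source_leaves_per_founder < 2:
            raise ValueError(
                "each founder needs >= 2 source leaves "
                "(one identical, one derived)"
            )
        if self.sink_shape not in ("star", "cherry-star"):
            raise ValueError(f"unknown sink_shape {self.sink_shape!r}")
        if self.n_background_clades < 0:
            raise ValueError("n_background_clades must be >= 0")


@dataclass
class SimDataset:
    """A generated dataset plus its ground truth."""

    newick: str
    metadata: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    def as_phylo_tree(self) -> PhyloTree:
        return tree_io.parse_tree(self.newick, self.metadata)


def _mutations(rng: np.random.Generator, years: float, ypm: float) -> int:
    return int(rng.poisson(years / ypm)) if years > 0 else 0


class _Builder:
    """Accumulates nodes, sample ids and metadata rows during simulation."""

    def __init__(self, config: SimConfig):
        self.config = config
        self.meta_rows: list[tuple[str, str, str]] = []
        self._n_src = 0
        self._n_snk = 0

    def source_leaf(self, mutations: int, region: str) -> dendropy.Node:
        self._n_src += 1
        sid = f"SRC{self._n_src:04d}"
        nd = dendropy.Node()
        nd._sample_id = sid
        nd._mut = mutations
        self.meta_rows.append((sid, region, f"{region} population"))
        return nd

    def sink_leaf(self, mutations: int, population: str) -> dendropy.Node:
        self._n_snk += 1
        sid = f"SNK{self._n_snk:04d}"
        nd = dendropy.Node()
        nd._sample_id = sid
        nd._mut = mutations
        self.meta_rows.append((sid, self.config.sink_region, population))
        return nd

    @staticmethod
    def internal(mutations: int, children) -> dendropy.Node:
        nd = dendropy.Node()
        nd._sample_id = None
        nd._mut = mutations
        for c in children:
            nd.add_child(c)
        return nd


def simulate_source_tree(
    config: SimConfig, rng: np.random.Generator | None = None
):
    """Build the source tree with designated (still sink-free) founder nodes.

    Returns ``(root_node, builder, founder_sites)`` where
    ``founder_sites`` is a list of ``(node, EpochSpec)`` pairs marking
    where sink subtrees will attach.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    b = _Builder(config)
    ypm = config.years_per_mutation
    depth = config.source_clade_depth_years
    clade_roots: list[dendropy.Node] = []
    founder_sites = []
    for spec in config.epochs:
        for _ in range(spec.n_founders):
            children = [b.source_leaf(0, spec.source_region)]
            for _ in range(config.source_leaves_per_founder - 1):
                m = max(1, _mutations(rng, depth, ypm))
                children.append(b.source_leaf(m, spec.source_region))
            founder = b.internal(0, children)
            founder_sites.append((founder, spec))
            clade_roots.append(founder)
    for _ in range(config.n_background_clades):
        region = SOURCE_REGIONS[int(rng.integers(len(SOURCE_REGIONS)))]
        tips = [
            b.source_leaf(_mutations(rng, depth, ypm), region)
            for _ in range(2)
        ]
        clade_roots.append(b.internal(0, tips))
    # random binary join of clades into one rooted backbone
    while len(clade_roots) > 1:
        i, j = sorted(rng.choice(len(clade_roots), size=2, replace=False))
        right = clade_roots.pop(int(j))
        left = clade_roots.pop(int(i))
        for child in (left, right):
            child._mut = _mutations(rng, config.join_branch_years, ypm)
        clade_roots.append(_Builder.internal(0, [left, right]))
    root = clade_roots[0]
    # founder-site branch mutations were provisional 0 on clade roots;
    # the joining loop has already redrawn them where clades were merged
    return root, b, founder_sites


def inject_founders(
    root: dendropy.Node,
    builder: _Builder,
    founder_sites,
    config: SimConfig,
    rng: np.random.Generator,
) -> SimDataset:
    """Attach sink subtrees at every founder site and finalise the dataset."""
    ypm = config.years_per_mutation
    truth_rows = []
    pops = config.sink_populations
    for fi, (founder, spec) in enumerate(founder_sites):
        population = pops[fi % len(pops)]
        sink_ids = []
        k = spec.sink_per_founder
        t = spec.time_years
        if config.sink_shape == "star":
            for _ in range(k):
                leaf = builder.sink_leaf(_mutations(rng, t, ypm), population)
                founder.add_child(leaf)
                sink_ids.append(leaf._sample_id)
        else:  # cherry-star: paired tips under a half-depth stem
            i = 0
            while i + 1 < k:
                tips = []
                for _ in range(2):
                    leaf = builder.sink_leaf(
                        _mutations(rng, t / 2, ypm), population
                    )
                    tips.append(leaf)
                    sink_ids.append(leaf._sample_id)
                cherry = _Builder.internal(
                    _mutations(rng, t / 2, ypm), tips
                )
                founder.add_child(cherry)
                i += 2
            if i < k:
                leaf = builder.sink_leaf(_mutations(rng, t, ypm), population)
                founder.add_child(leaf)
                sink_ids.append(leaf._sample_id)
        truth_rows.append((fi, founder, spec, sink_ids))

    # finalise: stable labels, taxa, edge lengths
    tn = dendropy.TaxonNamespace()
    counter = 0
    stack = [root]
    # preorder via explicit stack to label internals deterministically
    order = []
    while stack:
        nd = stack.pop()
        order.append(nd)
        stack.extend(reversed(nd.child_nodes()))
    for nd in order:
        if nd._sample_id is None:
            counter += 1
            nd.label = f"N{counter:04d}"
        else:
            nd.taxon = tn.new_taxon(nd._sample_id)
        if nd is not root:
            nd.edge.length = int(nd._mut)
    tree = dendropy.Tree(seed_node=root, taxon_namespace=tn)
    newick = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip() + "\n"

    metadata = pd.DataFrame(
        builder.meta_rows, columns=["sample_id", "region", "population"]
    )
    truth = pd.DataFrame(
        [
            {
                "founder_id": f"T{fi + 1:03d}",
                "node_id": founder.label,
                "true_time_years": spec.time_years,
                "true_region": spec.source_region,
                "n_sink": len(sink_ids),
                "sink_sample_ids": ",".join(sink_ids),
            }
            for fi, founder, spec, sink_ids in truth_rows
        ]
    )
    return SimDataset(
        newick=newick, metadata=metadata, truth=truth, config=config
    )


def simulate_dataset(config: SimConfig) -> SimDataset:
    """One-call generation: source tree, founder injection, finalisation.

    Fully deterministic in ``config.seed``: identical configs give
    byte-identical Newick, metadata and truth tables.
    """
    rng = np.random.default_rng(config.seed)
    root, builder, sites = simulate_source_tree(config, rng)
    return inject_founders(root, builder, sites, config, rng)


def write_dataset(dataset: SimDataset, outdir) -> dict[str, str]:
    """Write tree.nwk, metadata.tsv and truth.tsv under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "tree": os.path.join(outdir, "tree.nwk"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    with open(paths["tree"], "w") as fh:
        fh.write(dataset.newick)
    dataset.metadata.to_csv(paths["metadata"], sep="\t", index=False)
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed (convenience for replicates)."""
    return replace(config, seed=seed)
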