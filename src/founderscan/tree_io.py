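"""Read, validate and annotate mutation-count phylogenies.

The input substrate for founder analysis is a rooted tree whose branch
lengths are **integer mutation counts** (substitutions inferred on the
branch), not time. Leaves are bound to rows of a sample-metadata table
(``sample_id``, ``region``, ``population``); a :class:`RoleAssignment`
declares which regions constitute the migration *source* and which the
*sink*. After :func:`annotate_roles`, every node carries tallies of
source and sink descendant leaves, the precomputation on which founder
detection relies.

Trees are exchanged as Newick (one tree per file, branch lengths
mandatory, polytomies allowed); parsing and serialisation are delegated
to :mod:`dendropy`, and dendropy's ``Tree``/``Node`` objects are used
directly as the in-memory representation, decorated with the attributes
``node_id``, ``mutations``, ``sample_id``, ``role``, ``n_source`` and
``n_sink``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import pandas as pd

METADATA_COLUMNS = ("sample_id", "region", "population")

#: Tolerance for accepting a float branch length as an integer count.
INTEGER_TOLERANCE = 1e-6


class TreeError(ValueError):
    """Fatal problem with the tree, the metadata, or their binding."""


@dataclass(frozen=True)
class RoleAssignment:
    """Which geographic regions play source and which play sink.

    Regions belonging to neither set are ignored by all tallies (their
    samples remain in the tree but do not participate in the analysis).
    """

    source_regions: frozenset
    sink_regions: frozenset

    def __init__(self, source_regions, sink_regions):
        object.__setattr__(self, "source_regions", frozenset(source_regions))
        object.__setattr__(self, "sink_regions", frozenset(sink_regions))
        if not self.source_regions:
            raise TreeError("source_regions must be non-empty")
        if not self.sink_regions:
            raise TreeError("sink_regions must be non-empty")
        overlap = self.source_regions & self.sink_regions
        if overlap:
            raise TreeError(
                f"source and sink regions overlap: {sorted(overlap)}"
            )


class PhyloTree:
    """A rooted dendropy tree with integer mutation counts and sample bindings.

    Attributes set on every underlying :class:`dendropy.Node`:

    ``node_id``
        Stable identifier. Leaves use their ``sample_id``; internal nodes
        use their Newick label if present, else a preorder ``N%04d`` label.
    ``mutations``
        Integer count of substitutions on the branch into the node
        (0 for the root, which has no branch).
    ``sample_id`` / ``region`` / ``population``
        Leaf bindings from the metadata table (``None`` on internal nodes).
    ``role``
        ``"source"``, ``"sink"`` or ``None``; set by :func:`annotate_roles`.
    ``n_source`` / ``n_sink``
        Descendant-leaf tallies per role (a leaf counts itself); set by
        :func:`annotate_roles`.
    """

    def __init__(self, tree: dendropy.Tree, metadata: pd.DataFrame):
        self.tree = tree
        self.metadata = metadata
        self._index: dict[str, dendropy.Node] = {}
        self.roles: RoleAssignment | None = None
        counter = 0
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                nd.node_id = nd.sample_id
            else:
                if not nd.label:
                    while f"N{counter:04d}" in self._index:
                        counter += 1
                    nd.label = f"N{counter:04d}"
                nd.node_id = nd.label
            if nd.node_id in self._index:
                raise TreeError(f"duplicate node identifier {nd.node_id!r}")
            self._index[nd.node_id] = nd

    # -- accessors ---------------------------------------------------------

    @property
    def root(self) -> dendropy.Node:
        return self.tree.seed_node

    def nodes(self):
        """Preorder iterator over all nodes."""
        return self.tree.preorder_node_iter()

    def leaves(self):
        return self.tree.leaf_node_iter()

    def node(self, node_id: str) -> dendropy.Node:
        try:
            return self._index[node_id]
        except KeyError:
            raise TreeError(f"unknown node identifier {node_id!r}") from None

    def ancestors(self, nd: dendropy.Node):
        """Proper ancestors of ``nd``, nearest first, ending at the root."""
        cur = nd.parent_node
        while cur is not None:
            yield cur
            cur = cur.parent_node

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self.nodes())


def read_metadata(source) -> pd.DataFrame:
    """Read and validate the sample-metadata TSV.

    ``source`` may be a path or an open text handle. The table must have
    the header ``sample_id<TAB>region<TAB>population``, unique sample ids
    and non-empty regions.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TreeError(f"metadata is missing columns {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise TreeError(f"duplicate sample_id in metadata: {sorted(set(dup))}")
    if (df["region"].str.len() == 0).any():
        bad = df.loc[df["region"].str.len() == 0, "sample_id"].tolist()
        raise TreeError(f"empty region for samples {bad}")
    return df[list(METADATA_COLUMNS)].reset_index(drop=True)


def _as_mutation_count(length, where: str) -> int:
    if length is None:
        raise TreeError(f"missing branch length on the branch into {where}")
    if length < 0:
        raise TreeError(f"negative branch length {length} into {where}")
    rounded = round(length)
    if abs(length - rounded) > INTEGER_TOLERANCE:
        raise TreeError(
            f"branch length {length} into {where} is not an integer "
            f"mutation count (tolerance {INTEGER_TOLERANCE})"
        )
    return int(rounded)


def parse_tree(newick_text: str, metadata: pd.DataFrame) -> PhyloTree:
    """Parse a Newick string into a validated, metadata-bound tree.

    Branch lengths must be present on every non-root branch and be
    non-negative integers (within ``1e-6``); every leaf label must match
    a ``sample_id`` in ``metadata``; duplicate leaf labels are fatal.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise TreeError(f"duplicate leaf label: {exc}") from exc
    except Exception as exc:
        raise TreeError(f"could not parse Newick input: {exc}") from exc
    meta = metadata.set_index("sample_id")
    seen: set[str] = set()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            nd.mutations = 0
        else:
            where = (
                nd.taxon.label if nd.taxon is not None
                else (nd.label or "an internal node")
            )
            nd.mutations = _as_mutation_count(nd.edge.length, where)
        nd.role = None
        nd.n_source = 0
        nd.n_sink = 0
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise TreeError("leaf without a label")
            sid = nd.taxon.label
            if sid in seen:
                raise TreeError(f"duplicate leaf label {sid!r}")
            seen.add(sid)
            if sid not in meta.index:
                raise TreeError(f"leaf {sid!r} has no metadata row")
            nd.sample_id = sid
            nd.region = meta.at[sid, "region"]
            nd.population = meta.at[sid, "population"]
        else:
            nd.sample_id = None
            nd.region = None
            nd.population = None
    return PhyloTree(tree, metadata)


def annotate_roles(ptree: PhyloTree, roles: RoleAssignment) -> PhyloTree:
    """Tally source/sink descendant leaves on every node, in place.

    A leaf counts itself; samples whose region belongs to neither role
    set contribute to neither tally. Fatal if either role ends up with
    zero leaves.
    """
    for nd in ptree.tree.postorder_node_iter():
        if nd.is_leaf():
            if nd.region in roles.source_regions:
                nd.role = "source"
                nd.n_source, nd.n_sink = 1, 0
            elif nd.region in roles.sink_regions:
                nd.role = "sink"
                nd.n_source, nd.n_sink = 0, 1
            else:
                nd.role = None
                nd.n_source, nd.n_sink = 0, 0
        else:
            nd.n_source = sum(c.n_source for c in nd.child_nodes())
            nd.n_sink = sum(c.n_sink for c in nd.child_nodes())
    root = ptree.root
    if root.n_sink == 0:
        raise TreeError("no sink lineages to analyse")
    if root.n_source == 0:
        raise TreeError("no source lineages to analyse")
    ptree.roles = roles
    return ptree


def to_newick(ptree: PhyloTree) -> str:
    """Serialise back to Newick with integer branch lengths and node labels."""
    for nd in ptree.tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = int(nd.mutations)
    text = ptree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return text.strip() + "\n"


def write_metadata(metadata: pd.DataFrame, dest) -> None:
    metadata.to_csv(dest, sep="\t", index=False)


def load_dataset(tree_path, metadata_path) -> PhyloTree:
    """Convenience: read metadata TSV and Newick file into a PhyloTree."""
    metadata = read_metadata(metadata_path)
    if isinstance(tree_path, io.TextIOBase):
        newick_text = tree_path.read()
    else:
        with open(tree_path) as fh:
            newick_text = fh.read()
    return parse_tree(newick_text, metadata)
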