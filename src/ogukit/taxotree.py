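"""Taxonomic hierarchies and their interplay with phylogenies.

Three input dialects are understood — Greengenes-style lineage strings,
the NCBI taxdump (``nodes.dmp``/``names.dmp``) and plain child-to-parent
maps — all normalised into one :class:`TaxonomyMap`.  On top of that sit
four operations: collapsing a feature table to a taxonomic rank, turning a
taxonomy into a tree with constant inter-rank branch lengths (a coarse
stand-in for a phylogeny in UniFrac), and collapsing a genome phylogeny so
each tip is a taxonomic unit at a chosen rank (which requires every unit to
be monophyletic).

Phylogenies are scikit-bio ``TreeNode`` objects throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from skbio import TreeNode

from .tables import FeatureTable

__all__ = [
    "RANKS",
    "TaxonomyMap",
    "TaxonomyError",
    "MonophylyError",
    "read_lineages",
    "read_taxdump",
    "read_parent_map",
    "collapse_table",
    "taxonomy_to_tree",
    "collapse_phylogeny",
    "read_newick",
    "write_newick",
    "UNASSIGNED_ID",
]

#: the seven standard ranks, shallow to deep
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}
_PREFIX_TO_RANK = {
    "k__": "kingdom",
    "p__": "phylum",
    "c__": "class",
    "o__": "order",
    "f__": "family",
    "g__": "genus",
    "s__": "species",
}

UNASSIGNED_ID = "Unassigned"


class TaxonomyError(ValueError):
    """Malformed or inconsistent taxonomy input."""


class MonophylyError(ValueError):
    """A taxonomic unit is not monophyletic in the phylogeny."""


@dataclass
class TaxonomyMap:
    """Node-to-parent hierarchy with ranks and display names.

    ``parent`` maps every non-root node to its parent; the root maps to
    itself.  ``rank`` is one of the seven standard ranks or ``"none"``;
    ranks never decrease toward the root along any parent chain.
    """

    parent: dict[str, str]
    rank: dict[str, str] = field(default_factory=dict)
    name: dict[str, str] = field(default_factory=dict)
    root: str = "root"

    def __post_init__(self) -> None:
        for node in self.parent:
            self._walk_to_root(node)

    def _walk_to_root(self, node: str) -> list[str]:
        chain = []
        seen = set()
        cur = node
        while True:
            if cur in seen:
                raise TaxonomyError(f"cyclic parent chain at node {cur!r}")
            seen.add(cur)
            chain.append(cur)
            parent = self.parent.get(cur)
            if parent is None:
                raise TaxonomyError(f"orphan node {cur!r}: parent missing from taxonomy")
            if parent == cur:
                return chain
            cur = parent

    def rank_of(self, node: str) -> str:
        return self.rank.get(node, "none")

    def name_of(self, node: str) -> str:
        return self.name.get(node, node)

    def ancestor_at(self, node: str, rank: str) -> str | None:
        """The ancestor of ``node`` (inclusive) at ``rank``, or None."""
        if rank not in _RANK_INDEX:
            raise TaxonomyError(f"unknown rank {rank!r}")
        if node not in self.parent:
            return None
        for anc in self._walk_to_root(node):
            if self.rank_of(anc) == rank:
                return anc
        return None

    def nodes_at(self, rank: str) -> list[str]:
        return [n for n in self.parent if self.rank_of(n) == rank]

    def lineage(self, node: str) -> list[str]:
        """Ancestors of ``node`` from just below the root down to itself."""
        chain = self._walk_to_root(node)
        return list(reversed(chain))


def read_lineages(source: str | Iterable[str]) -> TaxonomyMap:
    """Parse Greengenes-style lineage strings.

    Rows are ``genome_id<TAB>k__X; p__Y; ...``.  One node is created per
    distinct prefixed label per level; empty labels (``s__``) create no node,
    but an empty label with a nonempty label below it is rejected as
    malformed.  Genomes attach to their deepest nonempty label.
    """
    lines = open(source) if isinstance(source, str) else iter(source)
    parent: dict[str, str] = {"root": "root"}
    rank: dict[str, str] = {}
    name: dict[str, str] = {}
    try:
        for lineno, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise TaxonomyError(f"lineage line {lineno}: expected 2 columns")
            genome, lineage = fields
            labels = [tok.strip() for tok in lineage.split(";") if tok.strip() != ""]
            prev_node = "root"
            path: list[str] = []
            gap = False
            for label in labels:
                prefix = label[:3]
                if prefix not in _PREFIX_TO_RANK:
                    raise TaxonomyError(
                        f"lineage line {lineno}: unknown rank prefix in {label!r}"
                    )
                if label == prefix:  # empty label, e.g. "s__"
                    gap = True
                    continue
                if gap:
                    raise TaxonomyError(
                        f"lineage line {lineno}: nonempty label {label!r} below an "
                        "empty rank; gapped lineages are ambiguous"
                    )
                path.append(label)
                node_id = ";".join(path)
                if node_id not in parent:
                    parent[node_id] = prev_node
                    rank[node_id] = _PREFIX_TO_RANK[prefix]
                    name[node_id] = label
                elif parent[node_id] != prev_node:
                    raise TaxonomyError(
                        f"lineage line {lineno}: node {label!r} has conflicting parents"
                    )
                prev_node = node_id
            if genome in parent and parent[genome] != prev_node:
                raise TaxonomyError(
                    f"lineage line {lineno}: genome {genome!r} listed with two lineages"
                )
            parent[genome] = prev_node
            rank[genome] = "none"
            name[genome] = genome
    finally:
        if isinstance(source, str):
            lines.close()
    return TaxonomyMap(parent=parent, rank=rank, name=name, root="root")


def _read_dmp(source: str | Iterable[str]):
    lines = open(source) if isinstance(source, str) else iter(source)
    try:
        for line in lines:
            if not line.strip():
                continue
            yield [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
    finally:
        if isinstance(source, str):
            lines.close()


def read_taxdump(
    nodes: str | Iterable[str], names: str | Iterable[str] | None = None
) -> TaxonomyMap:
    """Parse the NCBI taxdump dialect (pipe-delimited dmp files).

    ``nodes.dmp`` supplies ids, parents and ranks; ``names.dmp`` supplies
    scientific names (only rows of name class "scientific name" are used).
    The root is the node that is its own parent.  Nonstandard ranks map to
    ``"none"``.
    """
    parent: dict[str, str] = {}
    rank: dict[str, str] = {}
    name: dict[str, str] = {}
    root: str | None = None
    for fields in _read_dmp(nodes):
        if len(fields) < 3:
            raise TaxonomyError(f"nodes.dmp row has {len(fields)} fields (expected >= 3)")
        node_id, parent_id, node_rank = fields[0], fields[1], fields[2]
        parent[node_id] = parent_id
        rank[node_id] = node_rank if node_rank in _RANK_INDEX else (
            "kingdom" if node_rank == "superkingdom" else "none"
        )
        if node_id == parent_id:
            root = node_id
    if root is None:
        raise TaxonomyError("taxdump has no root (node that is its own parent)")
    for node_id, parent_id in parent.items():
        if parent_id not in parent:
            raise TaxonomyError(f"orphan node {node_id!r}: parent {parent_id!r} absent")
    if names is not None:
        for fields in _read_dmp(names):
            if len(fields) >= 4 and fields[3] == "scientific name":
                name[fields[0]] = fields[1]
    return TaxonomyMap(parent=parent, rank=rank, name=name, root=root)


def read_parent_map(
    source: str | Iterable[str], ranks: Mapping[str, str] | None = None
) -> TaxonomyMap:
    """Parse a plain child<TAB>parent map (one line per child).

    Nodes that never appear as a child are roots; a single implicit root
    named ``root`` is added above them if there is more than one, keeping
    parent chains finite.  Optional ``ranks`` maps node id to rank.
    """
    parent: dict[str, str] = {}
    for lineno, line in enumerate(_iter_lines(source), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise TaxonomyError(f"parent map line {lineno}: expected 2 columns")
        child, par = fields
        if child in parent and parent[child] != par:
            raise TaxonomyError(f"parent map line {lineno}: conflicting parents for {child!r}")
        parent[child] = par
    tops = {p for p in parent.values() if p not in parent}
    if len(tops) == 1:
        root = tops.pop()
        parent[root] = root
    else:
        root = "root"
        if root in parent:
            raise TaxonomyError("multiple roots and the name 'root' is taken")
        for top in tops:
            parent[top] = root
        parent[root] = root
    rank = {n: (ranks.get(n, "none") if ranks else "none") for n in parent}
    return TaxonomyMap(parent=parent, rank=rank, root=root)


def _iter_lines(source: str | Iterable[str]) -> Iterable[str]:
    if isinstance(source, str):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def collapse_table(
    table: FeatureTable, taxonomy: TaxonomyMap, rank: str
) -> FeatureTable:
    """Sum each feature's counts into its ancestor at ``rank``.

    Features with no ancestor at that rank — including features absent from
    the taxonomy altogether — are pooled into the reserved feature
    ``Unassigned``, so per-sample sums are conserved exactly.
    """
    if rank not in _RANK_INDEX:
        raise TaxonomyError(f"unknown rank {rank!r}")
    groups: dict[str, str] = {}
    for feature in table.feature_ids:
        anc = taxonomy.ancestor_at(feature, rank) if feature in taxonomy.parent else None
        groups[feature] = taxonomy.name_of(anc) if anc is not None else UNASSIGNED_ID
    collapsed = table.data.groupby(
        pd.Index([groups[f] for f in table.feature_ids]), sort=True
    ).sum()
    collapsed.index.name = None
    return FeatureTable(collapsed, table.value_kind)


def taxonomy_to_tree(taxonomy: TaxonomyMap, tips: Iterable[str] | None = None) -> TreeNode:
    """Convert a taxonomy into a tree with constant inter-rank branch lengths.

    Every branch between adjacent ranks has length 1.0; lineages missing an
    intermediate rank are bridged by deterministic placeholder nodes
    (``<child>__incertae_<rank>``) so that all taxa at the same rank sit at
    the same tip-to-root path length.  Unranked leaf nodes (genomes) hang one
    unit below their deepest ranked ancestor's species-depth position, so
    genome tips are also depth-aligned.

    ``tips`` selects which leaf nodes to include (default: all leaves).
    """
    children: dict[str, list[str]] = {}
    for node, par in taxonomy.parent.items():
        if node != par:
            children.setdefault(par, []).append(node)
    if tips is None:
        leaves = [n for n in taxonomy.parent if n not in children]
    else:
        leaves = list(tips)
        for leaf in leaves:
            if leaf not in taxonomy.parent:
                raise TaxonomyError(f"requested tip {leaf!r} absent from taxonomy")

    root = TreeNode(name=taxonomy.name_of(taxonomy.root))
    root.length = None
    index: dict[tuple[str, ...], TreeNode] = {(): root}

    def get_node(path: tuple[str, ...]) -> TreeNode:
        if path in index:
            return index[path]
        parent_node = get_node(path[:-1])
        node = TreeNode(name=path[-1], length=1.0)
        parent_node.append(node)
        index[path] = node
        return node

    n_ranks = len(RANKS)
    for leaf in leaves:
        chain = taxonomy.lineage(leaf)  # root ... leaf
        ranked = [n for n in chain if taxonomy.rank_of(n) in _RANK_INDEX]
        # build the depth-aligned path of rank slots
        path: list[str] = []
        prev_idx = -1
        for node in ranked:
            idx = _RANK_INDEX[taxonomy.rank_of(node)]
            if idx <= prev_idx:
                raise TaxonomyError(
                    f"rank order violated on lineage of {leaf!r} at {node!r}"
                )
            label = taxonomy.name_of(node)
            for gap_idx in range(prev_idx + 1, idx):
                path.append(f"{label}__incertae_{RANKS[gap_idx]}")
            path.append(label)
            prev_idx = idx
        if taxonomy.rank_of(leaf) not in _RANK_INDEX:
            # unranked genome: pad to below the species slot
            label = taxonomy.name_of(leaf)
            for gap_idx in range(prev_idx + 1, n_ranks):
                path.append(f"{label}__incertae_{RANKS[gap_idx]}")
            path.append(label)
        get_node(tuple(path))
    return root


def collapse_phylogeny(
    tree: TreeNode, taxonomy: TaxonomyMap, rank: str
) -> TreeNode:
    """Collapse a genome phylogeny so each tip is a taxonomic unit at ``rank``.

    Tips are mapped to their ancestor at ``rank`` through the taxonomy; tips
    with no such ancestor are pruned.  Each unit must be monophyletic among
    the remaining tips: its clade (the MRCA of its genomes and everything
    below) is replaced by a single tip named for the unit, carrying the
    clade's stem branch length.  A non-monophyletic unit raises
    :class:`MonophylyError` naming the unit and the intruding tips.
    """
    if rank not in _RANK_INDEX:
        raise TaxonomyError(f"unknown rank {rank!r}")
    unit_of: dict[str, str] = {}
    for tip in tree.tips():
        if tip.name in taxonomy.parent:
            anc = taxonomy.ancestor_at(tip.name, rank)
            if anc is not None:
                unit_of[tip.name] = taxonomy.name_of(anc)
    if not unit_of:
        raise TaxonomyError(f"no tip of the tree has an ancestor at rank {rank!r}")
    work = tree.shear(list(unit_of)) if len(unit_of) < tree.count(tips=True) else tree.copy()
    members: dict[str, set[str]] = {}
    for tip_name, unit in unit_of.items():
        members.setdefault(unit, set()).add(tip_name)
    for unit in sorted(members):
        tips = members[unit]
        if len(tips) == 1:
            node = work.find(next(iter(tips)))
        else:
            node = work.lca(sorted(tips))
        clade_tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        intruders = clade_tips - tips
        if intruders:
            raise MonophylyError(
                f"taxonomic unit {unit!r} at rank {rank!r} is not monophyletic: "
                f"its clade also contains {sorted(intruders)}"
            )
        if node.parent is None:
            # every remaining tip belongs to this one unit; keep a proper
            # root with the unit as its single tip
            tip = TreeNode(name=unit, length=node.length)
            work = TreeNode(children=[tip])
        else:
            stem = node.length
            node.children = []
            node.name = unit
            node.length = stem
    return work


def read_newick(source: str | io.TextIOBase) -> TreeNode:
    """Read a rooted Newick tree, validating tip uniqueness and lengths."""
    if isinstance(source, str):
        tree = TreeNode.read(io.StringIO(source)) if "(" in source else TreeNode.read(source)
    else:
        tree = TreeNode.read(source)
    names = [t.name for t in tree.tips()]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels in tree: {sorted(dupes)}")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    return tree


def write_newick(tree: TreeNode, path: str | None = None) -> str:
    """Serialise a tree to Newick; returns the string, optionally writing it."""
    buf = io.StringIO()
    tree.write(buf)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
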