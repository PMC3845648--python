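"""Rooted trees with bootstrap supports, backed by dendropy for Newick I/O.

Gene-family trees carry per-leaf gene metadata (:class:`GeneRecord`);
internal node labels are interpreted as bootstrap support values in
[0, 100].  Algorithms in :mod:`c4recruit.delimit` operate on the small
:class:`Node` structure defined here so that pruning and support
semantics stay explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import dendropy

__all__ = [
    "GeneRecord",
    "Node",
    "NewickParseError",
    "parse_newick",
    "to_newick",
    "root_on_outgroup",
]


class NewickParseError(ValueError):
    """Raised when Newick text cannot be parsed or validated."""


@dataclass
class GeneRecord:
    """Metadata attached to a gene-tree leaf.

    ``chloroplast_predicted`` is carried as input metadata only (transit
    peptides are predicted upstream); ``is_query`` marks transcripts to be
    placed into reference lineages rather than used to define them.
    """

    gene_id: str
    species_id: str
    cds_length_bp: int = 1
    chloroplast_predicted: Optional[bool] = None
    is_query: bool = False

    def __post_init__(self) -> None:
        if self.cds_length_bp <= 0:
            raise ValueError(
                f"cds_length_bp must be positive for {self.gene_id!r}"
            )


@dataclass
class Node:
    """A node of a rooted tree.

    ``support`` is a bootstrap percentage in [0, 100] or ``None`` when the
    input carried no label.  Leaves hold a label (the gene or species id)
    and optionally a :class:`GeneRecord`.
    """

    label: Optional[str] = None
    support: Optional[float] = None
    length: Optional[float] = None
    children: list["Node"] = field(default_factory=list)
    record: Optional[GeneRecord] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["Node"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def iter_nodes(self) -> Iterator["Node"]:
        """Preorder traversal over all nodes of the subtree."""
        yield self
        for child in self.children:
            yield from child.iter_nodes()

    def leaf_labels(self) -> list[str]:
        return [lf.label for lf in self.leaves()]

    def find_leaf(self, label: str) -> Optional["Node"]:
        for lf in self.leaves():
            if lf.label == label:
                return lf
        return None

    def copy(self) -> "Node":
        return Node(
            label=self.label,
            support=self.support,
            length=self.length,
            children=[c.copy() for c in self.children],
            record=self.record,
        )


def _support_from_label(label: Optional[str]) -> Optional[float]:
    if label is None or label == "":
        return None
    try:
        value = float(label)
    except ValueError as exc:
        raise NewickParseError(
            f"internal node label {label!r} is not a numeric bootstrap support"
        ) from exc
    if not 0.0 <= value <= 100.0:
        raise NewickParseError(
            f"bootstrap support {value} outside [0, 100]"
        )
    return value


def _convert(dnode: dendropy.Node) -> Node:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon else dnode.label
        return Node(label=label, length=dnode.edge.length)
    node = Node(
        support=_support_from_label(dnode.label),
        length=dnode.edge.length,
        children=[_convert(c) for c in dnode.child_nodes()],
    )
    return node


def parse_newick(text: str) -> Node:
    """Parse one Newick tree, reading internal node labels as supports.

    Raises :class:`NewickParseError` on malformed input or on a support
    value outside [0, 100].
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    root = _convert(dtree.seed_node)
    if root.is_leaf and root.label is None:
        raise NewickParseError("empty tree")
    return root


def to_newick(root: Node, include_lengths: bool = False) -> str:
    """Serialize a tree; supports are written as internal node labels."""

    def fmt(node: Node) -> str:
        if node.is_leaf:
            out = node.label or ""
        else:
            inner = ",".join(fmt(c) for c in node.children)
            sup = ""
            if node.support is not None:
                sup = (
                    str(int(node.support))
                    if float(node.support).is_integer()
                    else repr(node.support)
                )
            out = f"({inner}){sup}"
        if include_lengths and node.length is not None:
            out += f":{node.length:g}"
        return out

    return fmt(root) + ";"


def attach_records(root: Node, records: dict[str, GeneRecord]) -> None:
    """Attach gene metadata to leaves by gene id (leaf label)."""
    for leaf in root.leaves():
        if leaf.label in records:
            leaf.record = records[leaf.label]


def annotate_gene_leaves(
    gene_root: Node,
    species_ids: Sequence[str],
    query_prefix: str = "QUERY",
) -> None:
    """Attach :class:`GeneRecord` metadata to leaves of a tree read from
    plain Newick, inferring each gene's species from its label.

    A label matches species ``s`` when it equals ``s`` or carries ``s``
    as a prefix/suffix separated by ``|`` or ``_`` (e.g. ``Setaria|g1``
    or ``FAM1_L2_Setaria``).  Labels starting with ``query_prefix`` are
    marked as query transcripts; labels matching no species are left as
    they are (treated as outgroup genes downstream).
    """
    species = sorted(species_ids, key=len, reverse=True)
    for leaf in gene_root.leaves():
        label = leaf.label or ""
        if label.startswith(query_prefix):
            leaf.record = GeneRecord(
                gene_id=label, species_id="?", is_query=True
            )
            continue
        for s in species:
            if (
                label == s
                or any(label.startswith(s + sep) for sep in "|_")
                or any(label.endswith(sep + s) for sep in "|_")
            ):
                leaf.record = GeneRecord(gene_id=label, species_id=s)
                break


def species_of_leaf(leaf: Node) -> str:
    """Species id of a leaf: its record's species, else its label."""
    if leaf.record is not None:
        return leaf.record.species_id
    return leaf.label


def root_on_outgroup(root: Node, outgroup_species: Sequence[str]) -> Node:
    """Reroot so that the named outgroup species form one side of the root.

    The outgroup leaves must already be monophyletic in the input (the
    usual case for trees rooted upstream with eudicot outgroups); this
    helper re-hangs the tree on the edge above that clade rather than
    performing a full reroot search.
    """
    wanted = set(outgroup_species)
    if not wanted:
        raise ValueError("outgroup_species must be nonempty")

    target = None
    for node in root.iter_nodes():
        sp = {species_of_leaf(lf) for lf in node.leaves()}
        if sp == wanted:
            target = node
            break
    if target is None:
        raise ValueError(
            f"no clade with exactly the outgroup species {sorted(wanted)}"
        )
    if target is root or target in root.children:
        return root  # already root-adjacent

    def remove_path(node: Node) -> Optional[Node]:
        """Return *node* with the target clade removed, collapsing
        unifurcations (the surviving child keeps its own support)."""
        if node is target:
            return None
        if node.is_leaf:
            return node
        kept = [remove_path(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if len(kept) == 1:
            return kept[0]
        node.children = kept
        return node

    rest = remove_path(root)
    return Node(children=[target, rest])
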