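"""Ortholog-lineage delimitation on gene-family trees.

A gene lineage is an ortholog group: a clade of (non-query) grass genes
whose internal structure is compatible with the species tree.  Lineages
are delimited as the *maximal* such clades whose own bootstrap support
passes a threshold ``tau`` (clades adjacent to the root, and single
leaves, are exempt from the support requirement, so the output always
partitions the reference genes).  Query transcripts are afterwards placed
into lineages when they nest unambiguously inside one lineage's clade.

Compatibility of a clade with the species tree requires

(a) within the clade, the genes of each species are monophyletic (recent
    within-species duplicates thus stay inside one lineage), and
(b) every clade-internal grouping supported at >= tau corresponds, after
    collapsing each species' genes to a single tip, to a clade of the
    species tree restricted to the species present; conflicts *below* the
    support threshold do not count against compatibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .trees import Node, species_of_leaf

__all__ = [
    "GeneLineage",
    "UNASSIGNED",
    "is_species_compatible",
    "delimit_lineages",
    "assign_query",
]

UNASSIGNED = "UNASSIGNED"


@dataclass
class GeneLineage:
    """An ortholog group: one clade's members keyed by species."""

    family_id: str
    lineage_id: str
    members: dict[str, list[str]] = field(default_factory=dict)
    support: Optional[float] = None

    def gene_ids(self) -> list[str]:
        return [g for genes in self.members.values() for g in genes]

    def species(self) -> set[str]:
        return set(self.members)


def _species_clusters(species_root: Node) -> list[frozenset[str]]:
    return [
        frozenset(lf.label for lf in node.leaves())
        for node in species_root.iter_nodes()
    ]


def _is_reference(leaf: Node, species_leafset: set[str]) -> bool:
    rec = leaf.record
    if rec is not None and rec.is_query:
        return False
    return species_of_leaf(leaf) in species_leafset


def restrict_to_references(root: Node, species_root: Node) -> Optional[Node]:
    """Copy of the gene tree keeping only non-query leaves of species present
    in the species tree.

    Unifurcations left by the pruning are collapsed; the surviving child
    keeps its own support (the removed node's support described a clade
    that included pruned leaves).
    """
    species_leafset = {lf.label for lf in species_root.leaves()}

    def prune(node: Node) -> Optional[Node]:
        if node.is_leaf:
            return node if _is_reference(node, species_leafset) else None
        kept = [prune(c) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            return kept[0]
        return Node(
            support=node.support,
            length=node.length,
            children=kept,
        )

    return prune(root.copy())


def is_species_compatible(
    clade: Node, species_root: Node, tau: float = 70.0
) -> bool:
    """True when a clade of non-query gene leaves is an acceptable ortholog
    group with respect to the species tree (see module docstring)."""
    leaves = list(clade.leaves())
    species_by_leaf = [species_of_leaf(lf) for lf in leaves]
    present = set(species_by_leaf)

    # (a) per-species monophyly inside the clade
    node_leafsets = {
        id(node): frozenset(lf.label for lf in node.leaves())
        for node in clade.iter_nodes()
    }
    all_leafsets = set(node_leafsets.values())
    genes_per_species: dict[str, set[str]] = {}
    for lf, sp in zip(leaves, species_by_leaf):
        genes_per_species.setdefault(sp, set()).add(lf.label)
    for sp, genes in genes_per_species.items():
        if len(genes) > 1 and frozenset(genes) not in all_leafsets:
            return False

    # (b) supported internal groupings must match the restricted species tree
    restricted = {
        frozenset(c & present)
        for c in _species_clusters(species_root)
        if c & present
    }
    for node in clade.iter_nodes():
        if node is clade or node.is_leaf:
            continue
        if node.support is None or node.support < tau:
            continue
        sp_set = frozenset(species_of_leaf(lf) for lf in node.leaves())
        if sp_set not in restricted:
            return False
    return True


def delimit_lineages(
    gene_root: Node,
    species_root: Node,
    tau: float = 70.0,
    family_id: str = "family",
) -> list[GeneLineage]:
    """Delimit ortholog lineages as maximal supported species-compatible
    clades.

    Query leaves and leaves from species absent in the species tree are
    ignored; the returned lineages partition the remaining reference
    genes.  Lineage ids are ``"1", "2", ...`` in the tree's left-to-right
    clade order, which is deterministic for a given input.
    """
    ref = restrict_to_references(gene_root, species_root)
    if ref is None:
        raise ValueError("gene tree contains no reference (non-query) leaves")

    found: list[Node] = []

    def descend(node: Node, root_adjacent: bool) -> None:
        exempt = root_adjacent or node.is_leaf
        supported = exempt or (node.support is not None and node.support >= tau)
        if supported and is_species_compatible(node, species_root, tau):
            found.append(node)
            return
        for child in node.children:
            descend(child, root_adjacent=(node is ref))

    descend(ref, root_adjacent=True)

    lineages = []
    for i, clade in enumerate(found, start=1):
        members: dict[str, list[str]] = {}
        for lf in clade.leaves():
            members.setdefault(species_of_leaf(lf), []).append(lf.label)
        lineages.append(
            GeneLineage(
                family_id=family_id,
                lineage_id=str(i),
                members=members,
                support=clade.support,
            )
        )
    return lineages


def assign_query(
    gene_root: Node, lineages: list[GeneLineage]
) -> dict[str, str]:
    """Place each query transcript into a reference lineage, or UNASSIGNED.

    A query is assigned to lineage L when the smallest clade containing the
    query and at least one reference gene contains reference genes of L
    only; queries falling basal to the lineages, or bridging two lineages,
    are left unassigned (and are dropped from expression totals
    downstream).
    """
    gene_to_lineage = {
        g: lin.lineage_id for lin in lineages for g in lin.gene_ids()
    }

    parent: dict[int, Optional[Node]] = {id(gene_root): None}
    for node in gene_root.iter_nodes():
        for child in node.children:
            parent[id(child)] = node

    queries = [
        lf
        for lf in gene_root.leaves()
        if lf.record is not None and lf.record.is_query
    ]

    result: dict[str, str] = {}
    for q in queries:
        node: Optional[Node] = parent[id(q)]
        assigned = UNASSIGNED
        while node is not None:
            hit = {
                gene_to_lineage[lf.label]
                for lf in node.leaves()
                if lf.label in gene_to_lineage
            }
            if hit:
                assigned = hit.pop() if len(hit) == 1 else UNASSIGNED
                break
            node = parent[id(node)]
        result[q.label] = assigned
    return result


def lookup_query(gene_root: Node, query_id: str) -> Node:
    """Fetch a query leaf by id, raising ``KeyError`` when absent."""
    leaf = gene_root.find_leaf(query_id)
    if leaf is None:
        raise KeyError(f"query {query_id!r} not found in gene tree")
    return leaf
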