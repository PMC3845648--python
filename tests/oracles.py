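"""Independent brute-force oracles used to check the main implementations.

These deliberately use naive enumeration (all clades, all subsets, all
ordered tuples) rather than sharing logic with the package.
"""

from itertools import combinations, product

from c4recruit.delimit import restrict_to_references
from c4recruit.trees import Node, species_of_leaf


def _leafset(node: Node) -> frozenset:
    return frozenset(lf.label for lf in node.leaves())


def oracle_compatible(clade: Node, species_root: Node, tau: float) -> bool:
    """Set-based re-statement of species-tree compatibility."""
    leaves = list(clade.leaves())
    present = {species_of_leaf(lf) for lf in leaves}
    leafsets = {_leafset(n) for n in clade.iter_nodes()}

    by_species = {}
    for lf in leaves:
        by_species.setdefault(species_of_leaf(lf), set()).add(lf.label)
    for genes in by_species.values():
        if len(genes) > 1 and frozenset(genes) not in leafsets:
            return False

    restricted = set()
    for node in species_root.iter_nodes():
        c = frozenset(lf.label for lf in node.leaves()) & present
        if c:
            restricted.add(c)
    for node in clade.iter_nodes():
        if node is clade or node.is_leaf:
            continue
        if node.support is not None and node.support >= tau:
            spset = frozenset(species_of_leaf(lf) for lf in node.leaves())
            if spset not in restricted:
                return False
    return True


def oracle_delimit(gene_root: Node, species_root: Node, tau: float) -> set:
    """Exhaustive-clade delimitation: test every clade of the reference-
    restricted tree for the lineage predicate, keep the maximal ones, and
    return the partition as a set of frozensets of gene ids."""
    ref = restrict_to_references(gene_root, species_root)
    nodes = list(ref.iter_nodes())
    root_adjacent = {id(ref)} | {id(c) for c in ref.children}

    qualifying = []
    for node in nodes:
        exempt = id(node) in root_adjacent or node.is_leaf
        supported = exempt or (node.support is not None and node.support >= tau)
        if supported and oracle_compatible(node, species_root, tau):
            qualifying.append(_leafset(node))

    maximal = set()
    for s in qualifying:
        if not any(s < t for t in qualifying):
            maximal.add(s)
    return maximal


def oracle_prob_all_same(k: int, n_species: int) -> float:
    """Enumerate every ordered tuple of lineage draws."""
    hits = sum(
        1 for tup in product(range(k), repeat=n_species) if len(set(tup)) == 1
    )
    return hits / k**n_species


def oracle_exact_tail(sizes, n_species: int, observed: int) -> float:
    """Sum Bernoulli-success subset probabilities over all 2^m subsets."""
    probs = [k ** (1 - n_species) for k in sizes]
    m = len(probs)
    total = 0.0
    for r in range(observed, m + 1):
        for subset in combinations(range(m), r):
            term = 1.0
            for i in range(m):
                term *= probs[i] if i in subset else 1.0 - probs[i]
            total += term
    return min(total, 1.0) if observed > 0 else 1.0
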