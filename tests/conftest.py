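import numpy as np
import pytest

from c4recruit.simulate import SimulationConfig, generate_bundle
from c4recruit.trees import GeneRecord, Node, parse_newick

SPECIES_NEWICK = "((Brachypodium,Oryza),(Zea,(Setaria,Alloteropsis)));"


@pytest.fixture(scope="session")
def species_tree():
    return parse_newick(SPECIES_NEWICK)


@pytest.fixture(scope="session")
def noise_free_bundle():
    """Default-condition fixture bundle: published family sizes, planted
    recruitment in every family, exact (noiseless) counts."""
    return generate_bundle(SimulationConfig(seed=11))


def random_gene_tree(rng: np.random.Generator, n_leaves: int, species: list[str]):
    """Random rooted binary gene tree with random species labels and
    random bootstrap supports; used for oracle-equivalence tests."""
    leaves = []
    for i in range(n_leaves):
        sp = species[int(rng.integers(len(species)))]
        gid = f"g{i}_{sp}"
        leaves.append(
            Node(label=gid, record=GeneRecord(gene_id=gid, species_id=sp))
        )
    nodes = leaves[:]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        support = float(rng.integers(0, 101)) if rng.random() < 0.8 else None
        nodes.append(Node(support=support, children=[left, right]))
    return nodes[0]
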