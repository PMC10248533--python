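import numpy as np
import pytest

import get3atlas as g


@pytest.fixture(scope="session")
def toy3():
    return g.load_model("TOY3")


@pytest.fixture(scope="session")
def lg():
    return g.load_model("LG")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_tree(n_taxa: int, seed: int, depth: float = 0.6) -> "g.Phylogeny":
    """Random ultrametric tree helper used across test modules."""
    return g.simulate_species_tree(n_taxa, seed=seed, depth=depth)


@pytest.fixture(scope="session")
def toy3_msa(toy3):
    tree = g.read_newick(
        "(((A:0.2,B:0.3):0.15,(C:0.25,D:0.2):0.1):0.1,(E:0.3,F:0.2):0.05);")
    seqs = g.evolve_sequences(tree, 400, toy3, seed=11)
    return tree, g.AlignmentBlock([(s.id, s.residues) for s in seqs])
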