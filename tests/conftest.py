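import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from lgt_audit import composition, synthdata
from lgt_audit.treeio import tree_from_newick


@pytest.fixture(scope="session")
def species8():
    """An 8-species Yule tree reused across tree tests."""
    return synthdata.simulate_species_tree(8, seed=42)


@pytest.fixture(scope="session")
def two_species_profiles():
    """Two simulated species in the high-overlap (Table-1-like) regime."""
    def make(gc3, tag, seed):
        cfg = synthdata.SimulationConfig(
            genes_per_species=100, gc3_target=gc3, codon_bias_strength=1.0, seed=seed
        )
        seqs = synthdata.simulate_coding_sequences(cfg, tag, seed=seed)
        return composition.compute_profiles(seqs)

    return make(0.50, "spA", 11), make(0.53, "spB", 12)


@pytest.fixture
def quartet_trees():
    """The distinct unrooted 4-leaf topologies."""
    t1 = tree_from_newick("((a:1,b:1):1,(c:1,d:1):1);")
    t2 = tree_from_newick("((a:1,c:1):1,(b:1,d:1):1);")
    return t1, t2


@pytest.fixture
def rng():
    return np.random.default_rng(0)
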