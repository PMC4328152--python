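import numpy as np
import pytest
from hypothesis import settings

from karyosocial import synth_data
from karyosocial.phylo_core import Phylogeny

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def balanced_tree() -> Phylogeny:
    """((A,B),(C,D)) with unequal internal structure, ultrametric depth 1."""
    return Phylogeny.from_newick("((A:0.5,B:0.5):0.5,(C:0.7,D:0.7):0.3);")


@pytest.fixture(scope="session")
def small_dataset() -> synth_data.SyntheticDataset:
    cfg = synth_data.GeneratorConfig(n_tips=50)
    return synth_data.generate_dataset(cfg, seed=11)


def random_tree(rng: np.random.Generator, n_tips: int,
                ultrametric: bool = False) -> Phylogeny:
    """Random topology with random branch lengths for oracle comparisons."""
    cfg = synth_data.GeneratorConfig(n_tips=max(n_tips, 4), death_rate=0.0)
    base = synth_data.sim_tree(cfg, seed=int(rng.integers(2 ** 31)))
    if n_tips < base.n_tips:
        base = base.prune_to(base.tip_labels[:n_tips])
    if ultrametric:
        return base
    lengths = base.edge_length.copy()
    lengths[1:] = rng.uniform(0.05, 1.0, size=base.n_nodes - 1)
    return Phylogeny(base.parent, lengths, base.labels)
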