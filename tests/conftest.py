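import numpy as np
import pytest

from keystonet.syndata import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """A fast synthetic experiment: 400 genes, triplicates, planted effects."""
    return SimulationConfig(
        n_genes=400,
        n_perturbed=60,
        restored_fraction=0.5,
        effect_log2fc=3.0,
        block_sizes=(20, 20),
        n_pathways=6,
        pathway_size_range=(8, 15),
        planted_group_size=5,
        planted_group_pool=8,
        seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
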