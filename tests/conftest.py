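import numpy as np
import pytest

from melanomorph.synthetic import (
    SimulationConfig,
    TypeRegime,
    make_dataset,
    simulate_tree,
)


def small_regimes():
    # two origins per type so 8 disjoint clades fit in a mid-sized tree
    return [
        TypeRegime("solid_cylindrical", 2, 1.10, 0.25, False, False),
        TypeRegime("solid_flat", 2, 1.20, 0.45, True, False),
        TypeRegime("hollow_cylindrical", 2, 1.05, 0.35, False, True),
        TypeRegime("hollow_flat", 2, 2.20, 0.90, True, True),
    ]


@pytest.fixture(scope="session")
def default_dataset():
    """Paper-scale synthetic dataset: 96 species, 4 convergent types."""
    cfg = SimulationConfig(seed=42)
    return cfg, *make_dataset(cfg)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SimulationConfig(n_species=48, seed=7, type_regimes=small_regimes())
    return cfg, *make_dataset(cfg)


@pytest.fixture(scope="session")
def summaries(default_dataset):
    from melanomorph.morphometrics import summarize_table

    _, _, _, table = default_dataset
    return summarize_table(table)


@pytest.fixture(scope="session")
def tree32():
    cfg = SimulationConfig(n_species=32, seed=5)
    return simulate_tree(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
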