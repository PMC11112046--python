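import pytest

from ppamut.sequence_features import PropertyTable
from ppamut.synthetic import (SyntheticConfig, make_synthetic_mutation_dataset,
                              make_toy_structure)


@pytest.fixture(scope="session")
def property_table():
    return PropertyTable.default()


@pytest.fixture(scope="session")
def toy_structure():
    return make_toy_structure(seed=0)


@pytest.fixture(scope="session")
def synth_small():
    """Small synthetic dataset with a known linear ddG law."""
    return make_synthetic_mutation_dataset(
        SyntheticConfig(n_mutations=120, n_complexes=5, seed=7))
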