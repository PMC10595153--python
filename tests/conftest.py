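import numpy as np
import pytest

from fragsol import (
    ModelConfig,
    MolFraNetwork,
    SynthConfig,
    smiles_to_graph,
)
from fragsol.synthetic_data import generate_smiles


@pytest.fixture(scope="session")
def tiny_net():
    """A small deterministic network shared by read-only model tests."""
    return MolFraNetwork(ModelConfig(hidden_width=12, seed=11), dtype=np.float64)


@pytest.fixture(scope="session")
def generator_corpus():
    """120 seeded generator molecules with rings mixed in."""
    return generate_smiles(SynthConfig(n_molecules=120, seed=20, ring_prob=0.4))


@pytest.fixture()
def ethanol():
    return smiles_to_graph("CCO")


@pytest.fixture()
def benzene():
    return smiles_to_graph("c1ccccc1")


@pytest.fixture()
def aspirin():
    return smiles_to_graph("CC(=O)Oc1ccccc1C(=O)O")
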