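import pytest
from rdkit import Chem

from graphpka.chemgraph import build_paired_graph
from graphpka.data_pipeline import (
    DatasetRecord,
    SyntheticSpec,
    generate_synthetic_library,
    record_to_paired_graph,
    records_to_graphs,
)
from graphpka.ionization import remove_proton


@pytest.fixture(scope="session")
def small_library():
    """100 synthetic acid/base molecules with ground-truth pKa labels."""
    return generate_synthetic_library(SyntheticSpec(n_molecules=100, seed=11))


@pytest.fixture(scope="session")
def small_graphs(small_library):
    return records_to_graphs(small_library)


@pytest.fixture()
def acetic_pair():
    """(acid mol, base mol, center) for acetic acid / acetate."""
    acid = Chem.MolFromSmiles("CC(=O)O")
    base = remove_proton(acid, 3)
    return acid, base, 3


@pytest.fixture()
def acetic_graph(acetic_pair):
    acid, base, center = acetic_pair
    return build_paired_graph(acid, base, center, mode="full")


@pytest.fixture()
def amine_chain_graph():
    """12-heavy-atom amine chain; atom index equals bond distance."""
    return record_to_paired_graph(DatasetRecord("NCCCCCCCCCCC", 10.6, 0))
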