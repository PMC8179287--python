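import numpy as np
import pytest

from regioml.dmpnn import DescriptorConfig, DescriptorModel
from regioml.fixtures import (
    OracleSpec,
    generate_molecules,
    generate_selective_reactions,
    oracle_table,
)
from regioml.mol_graph import canonical_smiles


@pytest.fixture(scope="session")
def molecules():
    return generate_molecules(40, seed=1)


@pytest.fixture(scope="session")
def clean_table(molecules):
    return oracle_table(molecules, OracleSpec(seed=0))


@pytest.fixture(scope="session")
def toy_records():
    return generate_selective_reactions(120, seed=7)


@pytest.fixture(scope="session")
def toy_table(toy_records):
    smis = sorted(
        {canonical_smiles(s) for r in toy_records for s in r.reactant_smiles.split(".")}
    )
    return oracle_table(smis, OracleSpec(seed=0))


@pytest.fixture(scope="session")
def tiny_descriptor_results(clean_table):
    """A briefly trained descriptor model for plumbing tests."""
    cfg = DescriptorConfig(hidden=16, depth=2, head_hidden=16, epochs=4)
    return DescriptorModel(clean_table, config=cfg).fit(seed=0)
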