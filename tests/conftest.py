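import pytest

from protacdec import library_from_smiles

# pyridine--propylene--piperidine: the smallest degrader-shaped toy molecule
P1 = "c1ccc(nc1)CCCN1CCCCC1"


@pytest.fixture
def p1_smiles():
    return P1


@pytest.fixture
def p1_libs():
    """Single-entry libraries matching P1's two terminal moieties."""
    return (
        library_from_smiles(["c1ccncc1"], "warhead"),
        library_from_smiles(["C1CCNCC1"], "e3_ligand"),
    )
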