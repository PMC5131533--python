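import pandas as pd
import pytest

from carbotrait import load_fixture
from carbotrait.datamodel import GeneStateMatrix, PhenotypeMatrix


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture()
def toy_phenotypes():
    values = pd.DataFrame(
        [[1, 0], [1, 1], [0, 0], [0, 1]],
        index=["s1", "s2", "s3", "s4"], columns=["glucose", "ribose"])
    return PhenotypeMatrix(values, branch_of={"s1": "A", "s2": "A",
                                              "s3": "B", "s4": "B"})


@pytest.fixture()
def toy_genes():
    states = pd.DataFrame(
        [["I", "A"], ["I", "P"], ["P", "I"], ["P", "S"]],
        index=["s1", "s2", "s3", "s4"], columns=["gA", "gB"])
    return GeneStateMatrix(states)
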