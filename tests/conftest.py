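import pytest

from translokit.ontology import load_ontology
from translokit.scoring import ProteinFeatures, published_model
from translokit.synthetic_data import SyntheticSpec, make_cohort, make_interactome, make_ontology


CHAIN_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: cellular process root
namespace: biological_process

[Term]
id: GO:0000002
name: middle process
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: specific process
namespace: biological_process
is_a: GO:0000002
"""


@pytest.fixture(scope="session")
def chain_dag():
    """Three-term is_a chain: GO:0000003 -> GO:0000002 -> GO:0000001."""
    return load_ontology(CHAIN_OBO)


@pytest.fixture(scope="session")
def model_high():
    return published_model(precision="high")


@pytest.fixture(scope="session")
def model_table():
    return published_model(precision="table")


@pytest.fixture(scope="session")
def protein_a():
    """The worked example: 20 neighbours, two GO annotations, no bridgeness."""
    return ProteinFeatures(
        protein_id="protein_A",
        go_terms=frozenset({"GO:0009887", "GO:0005737"}),
        degree=20,
    )


@pytest.fixture(scope="session")
def spec0():
    return SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def dag0(spec0):
    return make_ontology(spec0)


@pytest.fixture(scope="session")
def graph0(spec0):
    return make_interactome(spec0)


@pytest.fixture(scope="session")
def cohort0(spec0, dag0, graph0):
    """Default planted-signal training cohort (160 positives, 139 negatives)."""
    cohort, annotations = make_cohort(spec0, dag0, graph0)
    return cohort
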