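import pytest

from pksline import datasets
from pksline.assembly import assemble
from pksline.labeling import calls_from_tables
from pksline.rules import default_rules
from pksline.tiling import default_precursor_rules

THRESHOLD = 3.0


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def precursor_rules():
    return default_precursor_rules()


@pytest.fixture(scope="session")
def akaeolide_cluster():
    return datasets.akaeolide_cluster()


@pytest.fixture(scope="session")
def lorneic_cluster():
    return datasets.lorneic_cluster()


@pytest.fixture(scope="session")
def akaeolide_product(akaeolide_cluster, rules):
    return assemble(akaeolide_cluster, rules)


@pytest.fixture(scope="session")
def lorneic_product(lorneic_cluster, rules):
    return assemble(lorneic_cluster, rules)


@pytest.fixture(scope="session")
def akaeolide_tables():
    return datasets.akaeolide_enrichment()


@pytest.fixture(scope="session")
def lorneic_tables():
    return datasets.lorneic_enrichment()


@pytest.fixture(scope="session")
def akaeolide_calls(akaeolide_tables):
    return calls_from_tables(akaeolide_tables, THRESHOLD)


@pytest.fixture(scope="session")
def lorneic_calls(lorneic_tables):
    return calls_from_tables(lorneic_tables, THRESHOLD)


@pytest.fixture(scope="session")
def akaeolide_graph():
    return datasets.akaeolide_graph()


@pytest.fixture(scope="session")
def lorneic_graph():
    return datasets.lorneic_graph()
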