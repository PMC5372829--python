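import pytest

from agpkit.io import load_at_gene_table, load_attribute_table


@pytest.fixture(scope="session")
def attribute_rows():
    return load_attribute_table()


@pytest.fixture(scope="session")
def at_genes():
    return load_at_gene_table()
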