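import pytest

from zfsite.tables import load_rank_tables, load_triplet_assay_table


@pytest.fixture(scope="session")
def assay_records():
    return load_triplet_assay_table()


@pytest.fixture(scope="session")
def rank_codes():
    return load_rank_tables()


@pytest.fixture(scope="session")
def sp1_code(rank_codes):
    return rank_codes["SP1"]
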