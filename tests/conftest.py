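import pytest

from eggbox import reference_compositions, write_composition_table


@pytest.fixture(scope="session")
def study_compositions():
    """The eight bundled gel samples, raw at% with traces still in."""
    return {c.sample_id: c for c in reference_compositions()}


@pytest.fixture()
def study_table_csv(tmp_path):
    """The bundled study table written as a long-format CSV file."""
    path = tmp_path / "study.csv"
    write_composition_table(reference_compositions(), path, dialect="long")
    return path
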