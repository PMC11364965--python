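import pytest

from hormonomics.compounds import load_fixture_db


@pytest.fixture(scope="session")
def fixture_db():
    return load_fixture_db()


@pytest.fixture
def write_csv(tmp_path):
    """Write CSV text to a temp file and return its path."""

    def _write(text, name="table.csv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write
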