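import pytest

from cpfdna.sequence_io import DnaRecord


@pytest.fixture
def write_text(tmp_path):
    """Write a named text file under tmp_path and return its path."""

    def _write(name: str, content: str):
        path = tmp_path / name
        path.write_text(content, encoding="utf-8")
        return path

    return _write


@pytest.fixture
def record():
    """Factory for quick DnaRecord construction."""

    def _record(residues: str, seq_id: str = "s1") -> DnaRecord:
        return DnaRecord(seq_id, residues)

    return _record
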