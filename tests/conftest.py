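import pytest
from hypothesis import settings

from leascan.seq_records import NucleotideSequence, ProteinSequence

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def fasta_file(tmp_path):
    """Write records to a temporary FASTA file and return its path."""

    def _write(records: dict[str, str], name: str = "test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def nt():
    def _make(bases: str, id: str = "seq"):
        return NucleotideSequence(id=id, bases=bases)

    return _make


@pytest.fixture
def prot():
    def _make(residues: str, id: str = "prot"):
        return ProteinSequence(id=id, residues=residues)

    return _make
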