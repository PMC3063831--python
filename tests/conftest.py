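import pytest

from setstruct.synthetic_data import scenario_suvh


@pytest.fixture(scope="session")
def suvh_family():
    """One simulated SUVH-like family shared across tests (fixed seed)."""
    return scenario_suvh(seed=1)


@pytest.fixture
def fasta_file(tmp_path):
    """Write FASTA content to a temp file and return its path."""

    def _write(content: str, name: str = "seqs.fasta"):
        p = tmp_path / name
        p.write_text(content)
        return p

    return _write
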