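import pytest

from genefam import synthetic_data


@pytest.fixture(scope="session")
def family():
    """The default synthetic family genome (7 chromosomes, 18 members
    in 14/1/3 clades, 50 decoys), shared across tests."""
    return synthetic_data.simulate_family_genome(seed=7)


@pytest.fixture()
def write_fasta(tmp_path):
    def _write(records: dict[str, str], name: str = "seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write
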