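import numpy as np
import pytest


@pytest.fixture
def write_fasta(tmp_path):
    """Factory writing a FASTA file from {name: sequence} pairs."""

    def _write(records, name="test.fa", width=60):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_name, seq in records.items():
                fh.write(f">{rec_name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
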