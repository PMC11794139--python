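import numpy as np
import pytest

from phasekit.sequence import ResidueSequence

# the 19-residue secretion signal peptide of the tick glycine-rich protein
SIGNAL_PEPTIDE = "MNRMFVLAATLALVGMVFA"


@pytest.fixture
def signal_peptide() -> ResidueSequence:
    return ResidueSequence(id="signal", residues=SIGNAL_PEPTIDE,
                           region_label="signal 1-19")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tmp_fasta(tmp_path):
    def _write(records: dict, name: str = "seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records.items():
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write
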