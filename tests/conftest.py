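import numpy as np
import pytest

from toxscreen.fingerprints import Fingerprint


def random_fingerprint(rng: np.random.Generator, density: float = 0.2) -> Fingerprint:
    bits = (rng.random(166) < density).astype(int)
    return Fingerprint(keys=tuple(int(b) for b in bits), backend="synthetic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def smi_file(tmp_path):
    """Small .smi library: 3 valid molecules."""
    p = tmp_path / "lib.smi"
    p.write_text("CCO\tethanol\nc1ccccc1\tbenzene\nCC(=O)O\tacetic_acid\n")
    return p


@pytest.fixture
def smi_file_with_bad(tmp_path):
    """6-line .smi library with one malformed SMILES."""
    p = tmp_path / "mixed.smi"
    p.write_text(
        "CCO\te1\nc1ccccc1\tb1\nC1CC\tbroken\nCC(=O)O\ta1\nCCN\tn1\nCCC\tp1\n"
    )
    return p
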