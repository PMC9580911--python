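import numpy as np
import pytest

from revfold.core import ModelConfig, ProteinRecord
from revfold.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_config():
    """Small model for fast structural tests."""
    return ModelConfig(nf=8, T=2, nLevels=2, seed=3)


@pytest.fixture
def toy_record():
    """A hand-built 4-residue record with a valid chain and degenerate PSSM."""
    coords = np.array([
        [0.0, 3.8, 7.6, 11.4],
        [0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0],
    ])
    pssm = np.zeros((20, 4))
    for i, aa_idx in enumerate([0, 1, 2, 3]):   # A, C, D, E
        pssm[aa_idx, i] = 1.0
    return ProteinRecord(id="toy", sequence="ACDE", pssm=pssm,
                         coords=coords, mask=np.ones(4, bool)).validate()


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SyntheticSpec(n_proteins=6, length_range=(16, 24), seed=42))
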