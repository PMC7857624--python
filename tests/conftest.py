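from pathlib import Path

import numpy as np
import pytest

from oclstm.bayes_opt import HyperparamPoint
from oclstm.cnn import build_architecture, train_cnn
from oclstm.io_encoding import encode_windows
from oclstm.synthetic import SyntheticConfig, generate_proteins, train_valid_test_split

DATA_DIR = Path(__file__).parent / "data"

TOY_PSSM_SCORES = np.array([
    [4, -1, -2, -2, 0, -1, -1, 0, -2, -1, -1, -1, -1, -2, -1, 1, 0, -3, -2, 0],
    [0, -3, -3, -3, 9, -3, -4, -3, -3, -1, -1, -3, -1, -2, -3, -1, -1, -2, -2, -1],
    [-2, -2, 1, 6, -3, 0, 2, -1, -1, -3, -4, -1, -3, -3, -1, 0, -1, -4, -3, -3],
], dtype=float).T  # 20 x 3


@pytest.fixture(scope="session")
def toy_pssm_path() -> Path:
    return DATA_DIR / "toy.pssm"


@pytest.fixture(scope="session")
def small_corpus():
    cfg = SyntheticConfig(n_proteins=24, length_range=(15, 30), seed=7)
    return generate_proteins(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_corpus):
    records, profiles = small_corpus
    return encode_windows(profiles, records, 13)


@pytest.fixture(scope="session")
def split_datasets():
    """Train/valid/test window datasets from a modest corpus with clear signal."""
    cfg = SyntheticConfig(n_proteins=60, length_range=(20, 40),
                          profile_signal=2.0, profile_noise_sd=0.5, seed=5)
    records, profiles = generate_proteins(cfg)
    parts = train_valid_test_split(records, profiles, (0.6, 0.2, 0.2), seed=5)
    datasets = tuple(encode_windows(p, r, 13) for r, p in parts)
    return parts, datasets


@pytest.fixture(scope="session")
def tiny_trained_cnn(split_datasets):
    """A quickly trained small CNN shared across tests that need a real model."""
    _, (ds_tr, ds_va, _) = split_datasets
    spec = build_architecture(1, 13, filter_base=16)
    hp = HyperparamPoint(3e-3, 0.9, 1e-6, 1)
    return train_cnn(spec, ds_tr, ds_va, hp, epochs=2, seed=0)
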