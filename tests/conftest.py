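import numpy as np
import pytest

from protclass import ProteinSequence, SVMConfig, SyntheticSpec, generate, loocv
from protclass.sequence_io import ALPHABET


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def random_sequences(rng):
    """200 random sequences over the canonical alphabet, lengths 5-60."""
    seqs = []
    letters = list(ALPHABET)
    for i in range(200):
        n = int(rng.integers(5, 61))
        seqs.append(ProteinSequence(id=f"r{i}", residues="".join(rng.choice(letters, size=n))))
    return seqs


@pytest.fixture(scope="session")
def small_dataset():
    """Separable 20/40 synthetic dataset used across classifier tests."""
    return generate(SyntheticSpec(n_pos=20, n_neg=40, length_range=(50, 120), effect=0.9, seed=11))


@pytest.fixture(scope="session")
def small_cv(small_dataset):
    """LOO CV result on the small separable dataset (computed once)."""
    return loocv(small_dataset, "AAC", SVMConfig())
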