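import pytest

from viscocann.synthetic import make_dataset
from viscocann.training import TrainConfig, train_fold


@pytest.fixture(scope="session")
def tiny_dataset():
    """Three noisy synthetic specimens (cheap, shared across tests)."""
    return make_dataset(n_specimens=3, seed=11)


@pytest.fixture(scope="session")
def trained_fold(tiny_dataset):
    """One moderately trained fold shared by model/relevance tests.

    Two specimens train, one validates; 250 epochs is enough for a clearly
    better-than-mean fit without dominating the suite runtime.
    """
    sp = tiny_dataset.specimens
    return train_fold(sp[:2], sp[2], TrainConfig(epochs=250, seed=21), fold=0)
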