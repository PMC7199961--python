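import numpy as np
import pytest

import chimeranet as cn
from chimeranet.synthetic_data import SynthConfig, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    # small but class-balanced; enough rows for splits in plumbing tests
    return SynthConfig(n_pos=150, n_neg=150, n_transcripts=10, seed=5)


@pytest.fixture(scope="session")
def small_table(small_config):
    table, _ = gen_dataset(small_config)
    return table


@pytest.fixture(scope="session")
def tiny_model(small_table):
    """A quickly trained model for plumbing tests (prediction quality is
    irrelevant; only shapes, determinism and serialization matter)."""
    rng = np.random.default_rng(5)
    tr, val, _ = cn.split_dataset(small_table, (240, 60, 0), rng)
    config = cn.TrainingConfig(seed=5, max_epochs=2, early_stop_patience=2)
    return cn.train(
        cn.build_architecture(), cn.encode_batch(tr), cn.encode_batch(val), config
    )
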