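import numpy as np
import pytest

import stcapsnet as sc


@pytest.fixture(scope="session")
def fixture_suite():
    return sc.make_fixture_suite(seed=0)


@pytest.fixture(scope="session")
def tiny_eset(fixture_suite):
    """8 trials, 8 channels, 128 samples."""
    return fixture_suite["tiny"]


@pytest.fixture(scope="session")
def tiny_model_config():
    """Model geometry matching the tiny fixture (8 ch, 128 samples)."""
    return sc.ModelConfig(
        n_channels=8, n_samples=128, F1=4, TI=9, D=2, F2=16,
        pool1=4, pool2=8, n_caps=4, d_caps=4, d_out=8,
    )


@pytest.fixture(scope="session")
def reduced_training_set():
    """High-SNR synthetic set at the reduced preset geometry (shared across
    the slower training tests)."""
    gen = sc.preset_gen_config("reduced", n_trials_per_class=100, snr_db=10.0, seed=42)
    return sc.generate_epochs(gen)
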