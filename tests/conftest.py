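"""Shared fixtures: small dense instances and the session-trained denoiser."""

import numpy as np
import pytest

from coil.denoiser import TrainingConfig, train_denoiser
from coil.fixtures import generate_training_patches, make_oracle_instance
from coil.sara import build_sara_dictionary


@pytest.fixture(scope="session")
def dict16():
    """SARA dictionary for 16x16 images (dense-backed)."""
    return build_sara_dictionary((16, 16))


@pytest.fixture(scope="session")
def instance16():
    """One dense 16x16 / M=64 instance at 30 dB with its ADMM reference."""
    inst = make_oracle_instance(64, (16, 16), 30.0, seed=11)
    return inst


@pytest.fixture(scope="session")
def trained_denoiser():
    """Denoiser trained at the reference desk-scale protocol.

    2,000 synthetic 32x32 patches, noise level upsilon = 10 grey levels,
    lambda found by doubling until the held-out max Jacobian norm is <= 1.
    Shared across the training-dependent tests because training takes
    minutes on one core.
    """
    patches = generate_training_patches(2000, 32, seed=0)
    cfg = TrainingConfig(upsilon=10.0, epochs=5, seed=0)
    return train_denoiser(patches, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
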