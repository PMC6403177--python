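"""Shared fixtures: phantom cases and a small trained network.

The trained model is session-scoped because training, although scaled
down (half architecture at base width 8, 32x32 patches, 8 synthetic
subjects), dominates the suite's runtime; every test that needs a
trained network shares it.
"""

from __future__ import annotations

import numpy as np
import pytest

from vesselseg.nn import UNet2D, UNetConfig, train
from vesselseg.phantom import PhantomConfig, generate_phantom
from vesselseg.sampling import SamplerConfig, sample_patches

N_TRAIN_SUBJECTS = 8
HELD_OUT_SEEDS = (100, 101)
TRAIN_PATCH_SIZE = 32


@pytest.fixture(scope="session")
def phantom_case():
    """One default phantom (64^3, ~0.9% vessel prevalence)."""
    return generate_phantom(PhantomConfig(seed=1))


@pytest.fixture(scope="session")
def held_out_cases():
    """Two phantoms never seen during training."""
    return [generate_phantom(PhantomConfig(seed=s)) for s in HELD_OUT_SEEDS]


@pytest.fixture(scope="session")
def training_patches():
    """~2,000 balanced 32x32 patches from 8 synthetic subjects."""
    pairs = []
    for s in range(N_TRAIN_SUBJECTS):
        volume, mask, label = generate_phantom(PhantomConfig(seed=s))
        cfg = SamplerConfig(
            patch_size=TRAIN_PATCH_SIZE,
            n_vessel_per_subject=125,
            n_background_per_subject=125,
            seed=100 + s,
        )
        pairs.extend(sample_patches(volume, label, mask, cfg))
    return pairs


@pytest.fixture(scope="session")
def trained_model(training_patches):
    """Half architecture at base width 8 fitted on the phantom patches."""
    cfg = UNetConfig(
        base_width=8,
        depth=4,
        patch_size=TRAIN_PATCH_SIZE,
        dropout_rate=0.0,
        learning_rate=1e-3,
        batch_size=16,
        epochs=8,
        seed=0,
    )
    model = UNet2D(cfg)
    train(model, training_patches, cfg)
    return model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
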