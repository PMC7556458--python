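"""Shared fixtures: tiny specs, the synthetic task, and trained desk-scale
recurrent models reused across the training-dependent tests."""

from __future__ import annotations

import numpy as np
import pytest

from rvt.network import init_params
from rvt.specs import ReducedScale, make_spec
from rvt.synth import SyntheticTaskConfig, generate_images
from rvt.training import TrainConfig, train

#: desk-scale problem sizes used throughout the suite
TINY_BL_SCALE = ReducedScale(
    base_features=(3, 4), base_kernels=(3, 3), input_size=(6, 6, 2),
    n_classes=3, timesteps=3,
)
TRAIN_SEEDS = (0, 1, 2)
TRAIN_EPOCHS = 30


@pytest.fixture(scope="session")
def tiny_bl_spec():
    return make_spec("BL", TINY_BL_SCALE)


@pytest.fixture(scope="session")
def tiny_bl_model(tiny_bl_spec):
    return init_params(tiny_bl_spec, np.random.default_rng(0))


@pytest.fixture(scope="session")
def synthetic_dataset():
    return generate_images(SyntheticTaskConfig(seed=0))


@pytest.fixture(scope="session")
def trained_bl_models(synthetic_dataset):
    """Tiny BL models trained on the synthetic task, one per seed.

    Returns (spec, [(model, log), ...], (X_val, y_val, difficulty_val)).
    """
    ds = synthetic_dataset
    Xtr, ytr, _, _ = ds.subset("train")
    Xva, yva, _, dva = ds.subset("val")
    spec = make_spec("BL", ReducedScale(timesteps=4, n_classes=10))
    runs = []
    for seed in TRAIN_SEEDS:
        config = TrainConfig(
            epochs=TRAIN_EPOCHS, batch_size=50, seed=seed,
            augment=False, preprocessed=True,
        )
        model, log = train(spec, (2 * Xtr - 1, ytr, 2 * Xva - 1, yva), config)
        runs.append((model, log))
    return spec, runs, (2 * Xva - 1, yva, dva)
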