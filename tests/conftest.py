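import numpy as np
import pytest

from usanomaly import (
    ModelConfig,
    PhantomConfig,
    ReconstructionModel,
    TrainConfig,
    generate_dataset,
    train_model,
)

# small architecture used by unit tests that need a real (not necessarily
# well-trained) model; image sizes divisible by 2^2
TINY_MODEL = dict(channels=(4, 8), latent_dim=8)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small 32x32 phantom split with visible lesions."""
    cfg = PhantomConfig(
        height=32, width=32, n_train=12, n_val=4, n_test=4,
        lesion_area_min_px=30, lesion_area_max_px=80,
        lesion_drop_min=0.5, lesion_drop_max=0.7, seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_trained_ae(tiny_dataset):
    """AE trained briefly on the tiny split; enough for deterministic inference."""
    cfg = TrainConfig(batch_size=8, epochs=3, seed=5, augment_gamma=False)
    model_cfg = ModelConfig(kind="ae", image_size=(32, 32), in_channels=1, **TINY_MODEL)
    model, history = train_model("ae", tiny_dataset, cfg, model_cfg)
    return model, history


@pytest.fixture()
def untrained_model():
    cfg = ModelConfig(kind="ae", image_size=(32, 32), in_channels=1, **TINY_MODEL)
    return ReconstructionModel(cfg, seed=0)
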