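import numpy as np
import pytest

from gliotask.encoder import EncoderConfig
from gliotask.phantom import PhantomSpec, generate_cohort
from gliotask.pipeline import AugmentConfig, TrainConfig, train


def micro_train_config(**overrides) -> TrainConfig:
    """Tiny configuration (16^3, embed 16, 1 block) for fast pipeline tests."""
    defaults = dict(
        learning_rate=1e-3, batch_size=4, epochs=4, seed=0,
        encoder=EncoderConfig(input_size=16, patch_size=4, embed_dim=16,
                              n_blocks=1, n_heads=2),
        mfeb_width=2,
        augment=AugmentConfig(rotate=False, shift=False, intensity=False,
                              flip=True, noise=True),
    )
    defaults.update(overrides)
    return TrainConfig(**defaults)


@pytest.fixture(scope="session")
def micro_cohort():
    spec = PhantomSpec(n_subjects=12, grid_size=16, mismatch_effect=2.0,
                       necrosis_effect=2.0, seed=5)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def micro_run(micro_cohort):
    return train(micro_cohort, micro_train_config())


@pytest.fixture(scope="session")
def scaled_cohort():
    """Cohort for the scaled-down end-to-end run (strong planted signals)."""
    spec = PhantomSpec(n_subjects=80, grid_size=32, mismatch_effect=2.0,
                       necrosis_effect=2.0, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def scaled_run(scaled_cohort):
    """Train the scaled-down model (32^3 patches, embed 48, 2 blocks) once.

    Shared by the planted-signal-recovery and explanation acceptance tests
    and by the trainability/smoke properties; this is the most expensive
    fixture in the suite (several minutes on one CPU).
    """
    cfg = TrainConfig(
        learning_rate=1e-3, batch_size=4, epochs=14, seed=0,
        encoder=EncoderConfig(input_size=32, patch_size=4, embed_dim=48,
                              n_blocks=2, n_heads=6),
        mfeb_width=4,
        augment=AugmentConfig(rotate=False, shift=False, intensity=True,
                              flip=True, noise=True),
    )
    return train(scaled_cohort, cfg)
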