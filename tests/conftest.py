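import numpy as np
import pytest

from summedstates import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A fast, fully featured study configuration for end-to-end tests."""
    return GeneratorConfig(
        n_voxels=150,
        n_states=8,
        n_targets=12,
        n_state_participants=6,
        n_person_participants=8,
        n_raters=20,
        n_behavior_participants=12,
        trials_per_participant=40,
        vocab_size=60,
        doc_length=400,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
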