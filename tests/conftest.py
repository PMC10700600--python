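import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=20, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_spec():
    from hypovol.phantom import PhantomSpec

    return PhantomSpec()


@pytest.fixture(scope="session")
def noiseless_volume():
    from hypovol.phantom import PhantomSpec, generate_phantom

    return generate_phantom(PhantomSpec(noise_sd=0.0, seed=3))


@pytest.fixture(scope="session")
def trained_target_model():
    """Segmenter trained once on desk-scale phantoms; shared across tests.

    Uses the default pipeline training conditions (12 labeled volumes,
    two held out for validation, contrast augmentation factor 1).
    """
    from hypovol.augment import AugmentSpec
    from hypovol.model import ModelConfig, TrainConfig
    from hypovol.phantom import CohortSpec, generate_cohort
    from hypovol.pipeline import _train_task

    volumes = generate_cohort(CohortSpec(n_control=6, n_case=6, seed=11))
    model, history = _train_task(
        volumes, "target", ModelConfig(),
        TrainConfig(max_epochs=6, patience=4, seed=7),
        AugmentSpec(factor=1, seed=3), init_seed=5, n_val=2)
    return model, history


@pytest.fixture(scope="session")
def heldout_volumes():
    from hypovol.phantom import CohortSpec, generate_cohort

    return generate_cohort(CohortSpec(n_control=4, n_case=4, seed=99))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
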