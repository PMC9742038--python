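import numpy as np
import pandas as pd
import pytest

from ageplace import synth
from ageplace.config import ScenarioConfig


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """Reduced scenario for fast module tests (same structure as defaults)."""
    return ScenarioConfig(
        n_areas=300, n_practices=60, n_survey=2400, seed=7
    )


@pytest.fixture(scope="session")
def population(small_config):
    return synth.generate_population(small_config)


@pytest.fixture(scope="session")
def survey_constraints(small_config, population):
    return synth.generate_survey_and_constraints(small_config, population)


@pytest.fixture(scope="session")
def prescribing_sources(small_config, population):
    return synth.generate_prescribing_sources(small_config, population)


@pytest.fixture(scope="session")
def latent_digital(small_config, population):
    return synth.latent_digital_percentages(small_config, population)


@pytest.fixture(scope="session")
def matrix_and_labels(small_config, population, prescribing_sources, latent_digital):
    _, _, latent_rates = prescribing_sources
    return synth.assemble_variable_matrix(
        small_config, population, latent_rates, latent_digital
    )


@pytest.fixture(scope="session")
def scaled_matrix(matrix_and_labels):
    from ageplace.preprocess import fit_transform_matrix

    matrix, labels = matrix_and_labels
    scaled, _ = fit_transform_matrix(matrix)
    return scaled, labels


@pytest.fixture(scope="session")
def blobs():
    """Two well-separated isotropic point clouds with known labels."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.0, 1.0, size=(60, 4))
    b = rng.normal(8.0, 1.0, size=(40, 4))
    X = np.vstack([a, b])
    y = np.array([0] * 60 + [1] * 40)
    return X, y
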