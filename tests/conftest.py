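"""Shared fixtures: the default synthetic cohort and its feature table.

The expensive artifacts (80-image cohort, its 120-value descriptors)
are session-scoped so the end-to-end tests share one computation.
"""

import numpy as np
import pytest

from melagabor import pipeline, synthetic_data


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study cohort: 80 images, 20% malignant, seed 7."""
    config = synthetic_data.SyntheticConfig(n_images=80, seed=7)
    return config, synthetic_data.generate_samples(config)


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    """(X, y) descriptor matrix of the default cohort."""
    _, samples = default_cohort
    return pipeline.features_from_samples(samples)


@pytest.fixture(scope="session")
def small_cohort():
    """A small, quick cohort for pipeline-level tests (24 images, seed 7)."""
    config = synthetic_data.SyntheticConfig(n_images=24, class_balance=0.25,
                                            seed=7)
    return config, synthetic_data.generate_samples(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
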