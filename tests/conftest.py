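import numpy as np
import pytest

from hypothegon import ClassifierConfig, StudyDesign, battery_predictions


@pytest.fixture(scope="session")
def design():
    return StudyDesign()


@pytest.fixture(scope="session")
def predictions(design):
    return battery_predictions(design)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def clf_cfg():
    return ClassifierConfig()


def random_simplex_points(rng, n):
    """Uniform points on the simplex (Dirichlet(1,1,1))."""
    return rng.dirichlet(np.ones(3), size=n)
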