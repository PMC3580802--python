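import numpy as np
import pytest

from ebdose import PopulationModel, TherapeuticWindow


@pytest.fixture
def model():
    return PopulationModel(
        mu_alpha=1.0,
        sigma_alpha2=0.09,
        sigma_eps2=0.04,
        beta=np.array([0.3]),
        d=1.0,
        covariate_names=("smoker",),
    )


@pytest.fixture
def plain_model():
    """No covariates, d = 1."""
    return PopulationModel(mu_alpha=0.0, sigma_alpha2=0.25, sigma_eps2=0.04)


@pytest.fixture
def window():
    return TherapeuticWindow(2.0, 6.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
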