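import numpy as np
import pytest

from depdyn.model import ModelParameters


@pytest.fixture(scope="session")
def baseline() -> ModelParameters:
    """The published Spain-scale rate baseline."""
    return ModelParameters.spain_baseline()


def random_valid_params(rng: np.random.Generator) -> ModelParameters:
    """A random parameter draw with beta1 > mu (saboteurs viable)."""
    mu = rng.uniform(0.005, 0.05)
    return ModelParameters(
        recruitment=rng.uniform(1.0, 1e5),
        saboteur_contact=rng.uniform(mu * 1.5, 1.0),
        depression_contact=rng.uniform(0.01, 1.0),
        saboteur_aggravation=rng.uniform(0.0, 1.0),
        progression=rng.uniform(0.05, 1.0),
        primary_uptake=rng.uniform(0.0, 0.5),
        secondary_uptake=rng.uniform(0.0, 0.5),
        recovery_nonpharm=rng.uniform(0.0, 1.0),
        recovery_pharm=rng.uniform(0.0, 1.0),
        depression_death=rng.uniform(0.0, 0.1),
        relapse=rng.uniform(0.0, 0.1),
        natural_death=mu,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
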