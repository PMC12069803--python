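import pytest

from enzystoich import default_regime, generate_samples, stoich_table
from enzystoich.stoichiometry import chemistry_from_frame, profiles_from_frame


@pytest.fixture(scope="session")
def regime30():
    """Default synthetic regime at 30 samples per season×management cell."""
    return default_regime(n_per_cell=30, seed=42)


@pytest.fixture(scope="session")
def synthetic30(regime30):
    activities, chemistry, truth = generate_samples(regime30)
    return activities, chemistry, truth


@pytest.fixture(scope="session")
def stoich30(synthetic30):
    activities, chemistry, _ = synthetic30
    return stoich_table(profiles_from_frame(activities),
                        chemistry_from_frame(chemistry))
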