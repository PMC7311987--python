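import matplotlib

matplotlib.use("Agg")

import pytest
from hypothesis import settings

import sf6duq as sq

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def uk_dataset():
    """One seeded UK-like synthetic study (no misspecification)."""
    return sq.generate_study(sq.uk_like_config(), seed=42)


@pytest.fixture(scope="session")
def uk_fit(uk_dataset):
    return sq.RandomEffectsModel.from_dataset(uk_dataset).fit()


@pytest.fixture(scope="session")
def uk_misspec_dataset():
    """UK-like study generated WITH state-level misspecification."""
    return sq.generate_study(sq.uk_like_config(sigma_delta=0.04), seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fast valuation study: 40 respondents x 4 of 12 states."""
    pool = sq.sample_state_pool(12, seed=3)
    return sq.generate_valuation_study(
        sq.default_true_params(),
        n_respondents=40,
        states_per_respondent=4,
        state_pool=pool,
        seed=3,
    )


@pytest.fixture(scope="session")
def measurement_sample():
    states, w = sq.population_state_weights()
    return sq.generate_measurement_sample(states, w, n=4596, seed=7)
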