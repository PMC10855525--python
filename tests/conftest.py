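import warnings

import pytest
from hypothesis import HealthCheck, settings

import tearvar as tv

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def default_dataset() -> tv.SyntheticDataset:
    """One full-size study at the default conditions."""
    return tv.generate_dataset(tv.SimConfig(seed=7))


@pytest.fixture(scope="session")
def injected_dataset() -> tv.SyntheticDataset:
    """Default conditions with exactly three reflex outliers per person."""
    return tv.generate_dataset(tv.SimConfig(seed=7, n_outliers_per_person=3))


@pytest.fixture(scope="session")
def clean_config() -> tv.SimConfig:
    """Small, fast configuration without outliers or missingness."""
    return tv.SimConfig(seed=3, n_proteins=60, outlier_probability=0.0,
                        missingness_midpoint=None, peptides_per_protein=3)


@pytest.fixture(scope="session")
def clean_dataset(clean_config) -> tv.SyntheticDataset:
    return tv.generate_dataset(clean_config)
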