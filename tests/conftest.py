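import pytest

from irhisto import PhantomConfig, WavenumberAxis, generate
from irhisto.acceptance import (
    cluster_count_experiment,
    kmeans_oracle_experiment,
    operator_oracle_experiment,
    pca_discrimination_experiment,
    corrmap_profile_experiment,
)

ACCEPTANCE_SEED = 1


@pytest.fixture(scope="session")
def default_axis():
    return WavenumberAxis.from_range(1800, 900, 4)


@pytest.fixture(scope="session")
def clean_phantom():
    """Degradation-free phantom: pixels equal their pure signatures."""
    return generate(PhantomConfig(
        shape=(64, 32), noise_sd=0.0, scatter_sigma=0.0,
        baseline_coeffs_sd=(0, 0, 0), vapor_amp=0.0, outlier_fraction=0.0,
        seed=123))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-degradation phantom at reduced size."""
    return generate(PhantomConfig(shape=(64, 32), seed=321))


@pytest.fixture(scope="session")
def cluster_run():
    return cluster_count_experiment(ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def pca_run():
    return pca_discrimination_experiment(ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def oracle_run():
    return operator_oracle_experiment(ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def corrmap_run():
    return corrmap_profile_experiment(ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def kmeans_oracle_run():
    return kmeans_oracle_experiment(ACCEPTANCE_SEED)
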