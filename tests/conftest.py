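import numpy as np
import pytest

from presynvar import (
    OutputNeuronParams,
    PlasticityParams,
    ProtocolParams,
    run_ensemble,
    sample_population,
)


@pytest.fixture(scope="session")
def default_population():
    return sample_population(50, seed=1)


@pytest.fixture(scope="session")
def variance_ensemble_10():
    """Ten variance-rule runs at full protocol defaults (shared across tests)."""
    return run_ensemble(
        PlasticityParams("variance"),
        OutputNeuronParams(),
        ProtocolParams(),
        n_runs=10,
        base_seed=3,
    )


@pytest.fixture(scope="session")
def covariance_ensemble_10():
    """Ten covariance-rule runs at full protocol defaults."""
    return run_ensemble(
        PlasticityParams("covariance"),
        OutputNeuronParams(),
        ProtocolParams(),
        n_runs=10,
        base_seed=3,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
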