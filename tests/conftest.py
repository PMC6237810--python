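import numpy as np
import pytest

from sde2d.electrophoresis import LadderSpec, MobilityModel, simulate_experiment


@pytest.fixture(scope="session")
def model():
    return MobilityModel()


@pytest.fixture(scope="session")
def ladder():
    return LadderSpec()


@pytest.fixture(scope="session")
def clean_result():
    """One shared clean-scenario simulation (expensive)."""
    return simulate_experiment("clean", seed=1)


@pytest.fixture(scope="session")
def apoptosis_result():
    return simulate_experiment(
        "apoptosis", params={"p_linker_cleave": 0.5, "ssb_in_linker_rate": 0.02}, seed=3
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
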