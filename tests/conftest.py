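import numpy as np
import pytest

from gemkin.network import (
    IRREVERSIBLE,
    InhibitionSpec,
    ModelConfig,
    build_gemcitabine_network,
)
from gemkin.synthetic import make_toy_chain


@pytest.fixture(scope="session")
def toy_chain3():
    """S0 -> S1 -> S2 -> S3 with distinct rates (closed-form oracle)."""
    return make_toy_chain(3, [1.0, 0.5, 0.25])


@pytest.fixture(scope="session")
def toy_rates3():
    return {"step_0": 1.0, "step_1": 0.5, "step_2": 0.25}


@pytest.fixture(scope="session")
def default_model():
    return build_gemcitabine_network()


@pytest.fixture(scope="session")
def default_config():
    return ModelConfig()


@pytest.fixture(scope="session")
def calibrated_model():
    from gemkin.model import control_model

    return control_model()


@pytest.fixture(scope="session")
def calibrated_state(calibrated_model):
    from gemkin.model import control_state

    return control_state(calibrated_model)


@pytest.fixture
def no_dcmpd_inhibition_config():
    return ModelConfig(
        inhibitions={
            "dCK": InhibitionSpec("dCK", "dCTP", 1e-6, 1.0),
            "RR": InhibitionSpec("RR", "dFdC-DP", 1e-7, IRREVERSIBLE),
            "dCMPD": InhibitionSpec("dCMPD", "dFdC-TP", 0.0, 1.0),
        }
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
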