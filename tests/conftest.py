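import numpy as np
import pytest

from crowdreport import ExperimentDesign, ObserverModel


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mixed_observer():
    """An observer producing all report strategies in flanked conditions."""
    return ObserverModel(p_target=0.4, p_average=0.2, p_sub_near=0.2,
                         p_sub_far=0.15, p_guess=0.05, noise_sd_deg=12.0)
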