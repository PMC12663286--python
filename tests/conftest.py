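import numpy as np
import pytest

from thermacup.model import CuppingStudy
from thermacup.synth import ErythemaGroupParams, KineticsParams, generate_study


@pytest.fixture(scope="session")
def noise_free_study():
    """Small noise-free synthetic study (4 darker + 1 lighter subjects)."""
    return generate_study(
        n_darker=4,
        n_lighter=1,
        seed=7,
        kinetics=KineticsParams().noise_free(),
        erythema_params=ErythemaGroupParams().noise_free(),
        render_optical=False,
    )


@pytest.fixture(scope="session")
def noise_free_results(noise_free_study):
    return CuppingStudy(dataset=noise_free_study).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
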