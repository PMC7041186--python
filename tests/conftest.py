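import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from housepi import Demography, EconParams, EpiParams, ModelParams, TreatmentPolicy


@pytest.fixture
def default_params() -> ModelParams:
    """Tabulated parameter set with the worked-example economy (C_c=30, C_t=250)."""
    return ModelParams(econ=EconParams(C_c=30.0, C_t=250.0))


@pytest.fixture
def default_demog() -> Demography:
    return Demography()


@pytest.fixture
def economics_off_params() -> ModelParams:
    """Hatted rates collapsed to base and treatment ineffective: plain two-group SIR."""
    epi = EpiParams(
        beta_hat_p=0.3, beta_hat_c=0.5,
        iota_hat_p=0.03, iota_hat_c=0.05,
        gamma_plus_p=0.1, gamma_plus_c=0.1,
    )
    return ModelParams(epi=epi, econ=EconParams(C_c=30.0, C_t=250.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
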