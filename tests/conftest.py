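import numpy as np
import pytest

from chemevo.chemostat import ChemostatConfig, StrainParams
from chemevo.competition import EmergenceSpec


@pytest.fixture
def parent():
    return StrainParams("parent", mu_max=0.7, K_M=0.1, biomass_yield=1.0)


@pytest.fixture
def mutant():
    return StrainParams("evolved", mu_max=0.55, K_M=0.01, biomass_yield=1.0)


@pytest.fixture
def reactor():
    return ChemostatConfig(D=0.5, S_in=25.0, V=60.0)


@pytest.fixture
def emergence():
    return EmergenceSpec(t_emerge=0.0, amount=5e-4, mode="frequency")


@pytest.fixture
def truth_params():
    return {
        "parent.mu_max": 0.7, "parent.K_M": 0.1, "parent.yield": 1.0,
        "mutant.mu_max": 0.55, "mutant.K_M": 0.01, "mutant.yield": 1.0,
        "emergence.amount": 5e-4, "emergence.t_emerge": 0.0,
    }


@pytest.fixture
def obs_generations():
    return np.arange(0.0, 445.0 + 1e-9, 20.0)
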