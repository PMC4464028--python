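import numpy as np
import pytest

from cscflow.models import CSCParameters, csc_model
from cscflow.sampling import ParameterSpec, lhs_sample


def csc_specs(base: CSCParameters, var_pct: float = 50.0) -> list[ParameterSpec]:
    """The population-model sampling scheme: P_sy on its full admissible
    range, every rate varied +-var_pct% around its baseline."""
    specs = [ParameterSpec("P_sy", bounds=(0.0, 1.0))]
    for name in CSCParameters.names()[1:]:
        specs.append(
            ParameterSpec(name, baseline=getattr(base, name),
                          variation_pct=var_pct, nonnegative=True)
        )
    return specs


@pytest.fixture(scope="session")
def csc_defaults() -> CSCParameters:
    return CSCParameters()


@pytest.fixture(scope="session")
def csc():
    return csc_model()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_uniform_specs() -> list[ParameterSpec]:
    return [
        ParameterSpec("a", bounds=(0.0, 1.0)),
        ParameterSpec("b", baseline=10.0, variation_pct=50.0),
        ParameterSpec("c", baseline=2.0, variation_pct=25.0),
    ]


@pytest.fixture
def small_design(small_uniform_specs):
    return lhs_sample(small_uniform_specs, 20, seed=99)
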