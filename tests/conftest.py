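import numpy as np
import pytest

from hteplan import AttritionSpec, CovariateSpec, HTEDesign, Mechanism


@pytest.fixture
def base_design() -> HTEDesign:
    """Reference scenario: m=20, outcome ICC 0.01, covariate ICC 0.1,
    unit variances, effect size 0.1, alpha 0.05, 80% power."""
    return HTEDesign(m=20, rho_y=0.01, rho_x=0.1, sigma2_y=1.0, sigma2_x=1.0,
                     sigma2_w=0.25, delta=0.1, alpha=0.05, power_target=0.8)


@pytest.fixture
def mcar_70(base_design) -> AttritionSpec:
    return AttritionSpec(mechanism=Mechanism.MCAR, pi=0.7, tau=0.05)


@pytest.fixture
def cont_cov() -> CovariateSpec:
    return CovariateSpec(kind="continuous", rho_x=0.1, sigma2_x=1.0, mean=0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230406)
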