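import numpy as np
import pytest

from recruitmap.core import GrowthParams, SurvivalForm, SurvivalParams


@pytest.fixture
def fig_growth() -> GrowthParams:
    """Slow Ford–Walford growth toward unit asymptote from a tiny settler."""
    return GrowthParams(K=0.01, phi_inf=1.0, phi_0=0.01)


@pytest.fixture
def exponential_params() -> SurvivalParams:
    return SurvivalParams(form=SurvivalForm.EXPONENTIAL, alpha=0.99, beta=0.5)


@pytest.fixture
def logistic_params() -> SurvivalParams:
    return SurvivalParams(form=SurvivalForm.LOGISTIC, alpha=0.99, beta=0.2)


@pytest.fixture
def hyperbolic_params() -> SurvivalParams:
    return SurvivalParams(form=SurvivalForm.HYPERBOLIC, alpha=0.99, beta=0.1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)
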