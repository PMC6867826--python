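import numpy as np
import pytest

from mutsim import DfeSpec, SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def std_params():
    """Small, fast scenario with the standard selection coefficients."""
    return SimParams(
        N=100, U_ben=1e-4, U_del=1e-2, s_ben=0.1, s_del=-0.1, m_fold=10,
        x0=0.1, base_seed=0,
    )


@pytest.fixture
def neutral_params():
    """Zero mutation rates: the modifier is strictly neutral."""
    return SimParams(
        N=100, U_ben=0.0, U_del=0.0, s_ben=0.1, s_del=-0.1, m_fold=1,
        x0=0.1, base_seed=0,
    )


@pytest.fixture
def constant_dfe():
    return DfeSpec(mode="constant", mean_ben=0.1, mean_del=-0.1)
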