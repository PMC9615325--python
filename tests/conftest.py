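import pytest
from hypothesis import strategies as st

from rumorctl import ModelParams, State

# benchmark parameter sets used throughout the numerical experiments


@pytest.fixture
def params_stable_free():
    """Set where the rumor dies out: Lambda*beta < mu^2."""
    return ModelParams(Lambda=0.5, beta=0.3, mu=0.5, alpha=0.4, q=0.6, tau=0.0, Ith=0.4)


@pytest.fixture
def params_sliding():
    """Set with both positive equilibria; threshold placement decides the regime."""
    return ModelParams(Lambda=0.7, beta=0.6, mu=0.1, alpha=0.4, q=0.6, tau=0.0, Ith=0.4)


@pytest.fixture
def params_comparison():
    """Set for the discontinuous-vs-saturated control comparison."""
    return ModelParams(Lambda=0.6, beta=0.5, mu=0.1, alpha=0.4, q=0.7, tau=0.0, Ith=0.145)


@pytest.fixture
def history():
    return State(1.0, 0.5, 0.5)


def rates_strategy():
    """Strictly positive rate constants in a physically sensible range."""
    pos = st.floats(min_value=0.05, max_value=2.0, allow_nan=False, allow_infinity=False)
    return st.builds(
        ModelParams,
        Lambda=pos,
        beta=pos,
        mu=st.floats(min_value=0.02, max_value=0.8),
        alpha=pos,
        q=pos,
        tau=st.floats(min_value=0.0, max_value=5.0),
        Ith=st.floats(min_value=0.01, max_value=2.0),
    )
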