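import numpy as np
import pytest

from elatools import CohortSpec, MEMParams, default_base_params, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ferro2():
    """N=2 ferromagnet: h=0, J12=2; minima at (−,−) and (+,+)."""
    return MEMParams(h=[0.0, 0.0], J=[[0.0, 2.0], [2.0, 0.0]])


@pytest.fixture
def params3():
    """A fixed generic N=3 model with nonzero biases and couplings."""
    h = np.array([0.3, -0.2, 0.1])
    J = np.array([[0.0, 0.5, -0.3], [0.5, 0.0, 0.2], [-0.3, 0.2, 0.0]])
    return MEMParams(h=h, J=J)


@pytest.fixture(scope="session")
def exchangeable_table():
    """Small exchangeable cohort (no participant structure), reused across tests."""
    spec = CohortSpec(
        n_participants=4,
        n_sessions=4,
        base_params=default_base_params(5),
        t_max=600,
        participant_sd=0.0,
        session_sd=0.0,
        seed=2024,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def structured_table():
    """Cohort with strong participant-level heterogeneity (fingerprint-like)."""
    spec = CohortSpec(
        n_participants=4,
        n_sessions=4,
        base_params=default_base_params(5),
        t_max=600,
        participant_sd=0.2,
        session_sd=0.05,
        seed=2025,
    )
    return generate_cohort(spec)
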