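import numpy as np
import pytest

import ctlsim as cs


@pytest.fixture(scope="session")
def motility() -> cs.MotilityModel:
    return cs.default_motility_model()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config() -> cs.SimulationConfig:
    """Tiny arena for fast structural tests (density comparable to default)."""
    return cs.SimulationConfig(
        X_dim=300.0, Y_dim=300.0, Z_dim=300.0, N_T=16, N_I=20, T_Sim=60.0
    )


@pytest.fixture(scope="session")
def quarter_config() -> cs.SimulationConfig:
    """Quarter-volume arena preserving the default cell densities.

    Used where acceptance-style checks are scaled down for test runtime.
    """
    return cs.SimulationConfig(X_dim=441.0, Y_dim=441.0, Z_dim=441.0, N_T=50, N_I=62)


def straight_line_motility(speed: float = 6.0) -> cs.MotilityModel:
    """Degenerate motility: fixed speed, zero turning angle."""
    point = lambda v: cs.BinnedDistribution(edges=np.array([v, v]), probabilities=np.array([1.0]))
    return cs.MotilityModel(speed_hist=point(speed), turn_hist=point(0.0))
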