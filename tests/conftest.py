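import numpy as np
import pytest

from mcflipflop import (
    SolverOptions,
    canonical_sequence,
    default_params,
    phi_of,
    simulate_protocol,
)
from mcflipflop.schedule import MINUTE

CANONICAL_BP_MIN = np.array([0.0, 180.0, 900.0, 1080.0, 1800.0])


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def canonical_bp():
    """Canonical scoring breakpoints t_0 .. t_4 in seconds."""
    return CANONICAL_BP_MIN * MINUTE


@pytest.fixture(scope="session")
def fast_opts():
    """Solver options for tests: fast but well within quadrature needs."""
    return SolverOptions(rtol=1e-9, save_dt=60.0)


@pytest.fixture(scope="session")
def canonical_schedule():
    return canonical_sequence(3, 12, 1)


@pytest.fixture(scope="session")
def reference_run(params, canonical_schedule, fast_opts):
    """One shared 30-h reference simulation at the default parameters."""
    traj = simulate_protocol(params, canonical_schedule, fast_opts)
    return traj, phi_of(traj)
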