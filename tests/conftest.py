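import numpy as np
import pytest

from emaxdesign import (EmaxParams, OptimizerConfig, compute_local_optima,
                        solve_simultaneous_d_optimal, theta7_ensemble)

# moderate swarm settings: every local solve is certified by the
# equivalence theorem regardless, so a smaller swarm only risks an error,
# never a silently wrong design
FAST_CFG = OptimizerConfig(swarm_size=30, iterations=150, restarts=2, seed=1)


@pytest.fixture(scope="session")
def theta4() -> EmaxParams:
    return EmaxParams(1.0, -1.0, 469.36, 4.0)


@pytest.fixture(scope="session")
def theta5() -> EmaxParams:
    return EmaxParams(1.0, -1.0, 310.60, 10.0)


@pytest.fixture(scope="session")
def theta7():
    return theta7_ensemble()


@pytest.fixture(scope="session")
def local_opts7(theta7):
    return compute_local_optima(theta7, 1000.0, FAST_CFG)


@pytest.fixture(scope="session")
def simultaneous7(theta7, local_opts7):
    return solve_simultaneous_d_optimal(theta7, 1000.0,
                                        OptimizerConfig(seed=1),
                                        local_opts=local_opts7)


def random_admissible_theta(rng: np.random.Generator) -> EmaxParams:
    """A random fit-admissible parameter vector for property tests."""
    return EmaxParams(
        e0=rng.uniform(-2, 2),
        emax=rng.choice([-1, 1]) * rng.uniform(0.2, 5),
        ec50=rng.uniform(20, 1000),
        h=rng.uniform(0.3, 10),
    )
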