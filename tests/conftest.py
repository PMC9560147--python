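import numpy as np
import pytest

from boundedplan import (MINI_GEOMETRY, SolverOptions, build_task, solve)
from boundedplan.information import (Hypothesis, capacity_grid,
                                     condition_information)

# Capacity values used for grid-based tests: one low-capacity point, one
# intermediate point on the rising part of the utility curve, and the
# maximal-capacity reference.
GRID_BETAS = (2.0, 20.0, 500.0)


@pytest.fixture(scope="session")
def mini_task():
    return build_task(MINI_GEOMETRY)


@pytest.fixture(scope="session")
def default_task():
    return build_task()


@pytest.fixture(scope="session")
def policy_max(default_task):
    """Max-capacity solution on the full task (deterministic)."""
    return solve(default_task, 500.0, 500.0, SolverOptions())


@pytest.fixture(scope="session")
def profiles_max(policy_max, default_task):
    return {h: condition_information(policy_max, default_task, h)
            for h in Hypothesis}


@pytest.fixture(scope="session")
def mini_grid(mini_task):
    return capacity_grid(mini_task, GRID_BETAS, GRID_BETAS,
                         opts=SolverOptions(max_iter=20000))


@pytest.fixture(scope="session")
def full_grid(default_task):
    """Capacity grid on the full task, shared by the recovery tests."""
    return capacity_grid(default_task, GRID_BETAS, GRID_BETAS,
                         opts=SolverOptions(max_iter=1200, tol=1e-9))
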