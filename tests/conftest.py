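import numpy as np
import pytest

from smilegames import (
    GeneratorParams,
    GoalSpec,
    build_mdp,
    make_partner_hazard,
    value_iteration,
)


@pytest.fixture(scope="session")
def default_params():
    return GeneratorParams()


@pytest.fixture(scope="session")
def truth_hazard(default_params):
    """Ground-truth responsive-mother hazard table."""
    return make_partner_hazard(default_params)


@pytest.fixture(scope="session")
def mother_only_plan(truth_hazard):
    """Optimal plan for an infant agent maximizing mother-only smiling."""
    goal = GoalSpec(target="mother_only", agent_role="infant")
    return value_iteration(build_mdp(truth_hazard, goal))


@pytest.fixture(scope="session")
def all_plans(truth_hazard):
    from smilegames import solve_goal_plans

    return solve_goal_plans(truth_hazard)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
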