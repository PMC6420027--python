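"""Shared fixtures.

The agent-population fixture is expensive (two conditions × 100 agents ×
10 training blocks) and session-scoped: population-level assertions all
read from the same frozen run.
"""

from __future__ import annotations

import numpy as np
import pytest

from goalbabbling.arm_model import build_task_geometry
from goalbabbling.goal_babbling import LearnerConfig, run_population
from goalbabbling.synthetic_human import HumanGeneratorParams, generate_session

POPULATION_SEED = 1
N_AGENTS = 100


@pytest.fixture(scope="session")
def geometry():
    return build_task_geometry()


@pytest.fixture(scope="session")
def agent_populations(geometry):
    """100 Goal Babbling agents per condition at the study parameters."""
    cfg = LearnerConfig(seed=POPULATION_SEED)
    return {
        cond: run_population(cond, cfg, geometry, n_agents=N_AGENTS)
        for cond in ("H1", "H2")
    }


@pytest.fixture(scope="session")
def synthetic_session(geometry):
    """One default synthetic human session (24 blocks, no missing trials)."""
    params = HumanGeneratorParams(condition="H1", missing_prob=0.0, seed=7)
    return generate_session(params, geometry)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
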