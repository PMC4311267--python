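"""Shared fixtures: packaged models, representative solutions, lineages.

The expensive objects (3000-minute stiff trajectories, full reduction
lineages) are session-scoped so the whole suite pays for each once.
"""

import pytest

from qssareduce import fixtures, integrate, reduce_iteratively
from qssareduce.simulate import CONTINUOUS_HORIZON


@pytest.fixture(scope="session")
def sm():
    return fixtures.build_sm()


@pytest.fixture(scope="session")
def continuous():
    return fixtures.continuous_protocol()


@pytest.fixture(scope="session")
def pulsed():
    return fixtures.pulsed_protocol()


@pytest.fixture(scope="session")
def sm_traj(sm, continuous):
    """Representative solution of the ten-variable model, saturating dose."""
    return integrate(sm, sm.initial_conditions, continuous, CONTINUOUS_HORIZON)


@pytest.fixture(scope="session")
def lineage_continuous(sm, continuous):
    """Default 6-step continuous-input reduction (order-1 rescue enabled)."""
    return reduce_iteratively(sm, continuous, n_steps=6)


@pytest.fixture(scope="session")
def lineage_pulsed(sm, pulsed):
    """4-step reduction against the pulse-entrained representative solution."""
    return reduce_iteratively(sm, pulsed, n_steps=4)


@pytest.fixture(scope="session")
def lineage_p1(sm, continuous):
    """Continuous-input lineage with first-order p and w."""
    return reduce_iteratively(sm, continuous, n_steps=6,
                              order_policy={"p": 1, "w": 1})


@pytest.fixture(scope="session")
def lineage_all1(sm, continuous):
    """The all-first-order lineage, driven along the documented sequence."""
    return reduce_iteratively(
        sm, continuous, n_steps=6,
        order_policy={"p": 1, "y": 1, "v": 1, "s": 1, "w": 1},
        sequence=list("zpyvsw"))
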