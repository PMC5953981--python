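"""Shared fixtures.

Simulation fixtures use a reduced fiber (6 mm, dx 0.2 mm → 30 cells, short
pre-pacing) so the whole suite stays fast; production defaults are
exercised once in the acceptance tests.  Expensive simulations are
session-scoped and reused.
"""

import numpy as np
import pytest

from cardiorisk import (
    BlockState,
    FiberConfig,
    VirtualIndividual,
    simulate_cell,
    simulate_fiber,
)

REDUCED_FIBER = dict(dx=0.2, length=6.0)


@pytest.fixture(scope="session")
def individual():
    return VirtualIndividual()


@pytest.fixture(scope="session")
def reduced_config():
    return FiberConfig(**REDUCED_FIBER)


@pytest.fixture(scope="session")
def endo_trace():
    """Paced endocardial cell at study defaults, short pre-pacing."""
    return simulate_cell("endo", n_beats=10)


@pytest.fixture(scope="session")
def baseline_fiber(reduced_config):
    """Unblocked reduced fiber, final of 2 coupled beats."""
    return simulate_fiber(config=reduced_config, n_beats=2, prepace_beats=10)


@pytest.fixture(scope="session")
def ikr_blocked_fiber(reduced_config):
    """Reduced fiber under 75% IKr block."""
    return simulate_fiber(
        config=reduced_config,
        block=BlockState({"IKr": 0.25}),
        n_beats=2,
        prepace_beats=10,
    )
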