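"""Shared fixtures.

The converged-run fixtures are session-scoped because each one costs a
>=600-s simulated run; every acceptance-level check reuses them.
"""

from __future__ import annotations

import numpy as np
import pytest

from spikecompete.netgen import make_fixture
from spikecompete.pipeline import RECIPES, run_recipe

CONVERGED_DURATION_S = 1200
RUN_SEED = 1


@pytest.fixture
def chain3():
    return make_fixture("chain3")


@pytest.fixture
def star5():
    return make_fixture("star5")


@pytest.fixture
def loop4():
    return make_fixture("loop4")


def _recipe(name: str, condition: str | None = None):
    specs = RECIPES[name]()
    if condition is None:
        return specs[0]
    return next(s for s in specs if s.name == condition)


@pytest.fixture(scope="session")
def baseline_10hz_run():
    """Converged 10-spk/s baseline run (competition regime)."""
    return run_recipe(_recipe("baseline_10hz"), seed=RUN_SEED, duration_s=CONVERGED_DURATION_S)


@pytest.fixture(scope="session")
def baseline_1hz_run():
    """Converged 1-spk/s run (no competition)."""
    return run_recipe(_recipe("baseline_1hz"), seed=RUN_SEED, duration_s=CONVERGED_DURATION_S)


@pytest.fixture(scope="session")
def wmax20_run():
    """10-spk/s run with the plastic upper bound raised to 20 mV."""
    return run_recipe(_recipe("sweep_wmax", "wmax_20"), seed=RUN_SEED, duration_s=CONVERGED_DURATION_S)


@pytest.fixture(scope="session")
def uniform_init_run():
    """10-spk/s run with uniform [3, 9] initial plastic weights."""
    return run_recipe(
        _recipe("init_distributions", "init_3_9"), seed=RUN_SEED, duration_s=CONVERGED_DURATION_S
    )


@pytest.fixture(scope="session")
def all_to_all_run():
    """10-spk/s run with all-to-all STDP spike interactions."""
    return run_recipe(_recipe("all_to_all"), seed=RUN_SEED, duration_s=CONVERGED_DURATION_S)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
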