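import numpy as np
import pytest

import microtrait as mt
from microtrait.scenarios import ScenarioConfig, build_analogs


@pytest.fixture(scope="session")
def guilds():
    return mt.default_guilds()


@pytest.fixture(scope="session")
def mean_analogs(guilds):
    return [mt.mean_traits(g) for g in guilds]


@pytest.fixture(scope="session")
def aob7(guilds):
    return mt.mean_traits(next(g for g in guilds if g.guild_id == "AOB(7)"))


@pytest.fixture(scope="session")
def coupled_run(mean_analogs):
    """Reference coupled run: pH 7.8, 20 C, no pulses, 180 days."""
    env = mt.EnvironmentState(
        tan=1.0e-5 / mt.nh3_fraction(7.8), ph=7.8, temperature=293.15
    )
    state = mt.initial_community(mean_analogs, env)
    return mt.integrate(state, 180.0), state
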