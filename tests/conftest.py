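import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import selfgrad as sg

settings.register_profile(
    "package", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def wt_trajectory():
    """Default wild-type run: uniform production, calibrated coupling."""
    return sg.simulate(sg.default_config())


@pytest.fixture(scope="session")
def mutant_trajectory():
    """Toddler-null run: no production, random motility only."""
    return sg.simulate(sg.mutant_config())


@pytest.fixture(scope="session")
def coarse_config():
    """Coarser-grid wild-type configuration used for fitting round trips."""
    return sg.default_config(grid=sg.SpatialGrid(600.0, 40))


@pytest.fixture(scope="session")
def coarse_trajectory(coarse_config):
    return sg.simulate(coarse_config)


@pytest.fixture(scope="session")
def agent_tracks_200(coarse_config, coarse_trajectory):
    """200 field-consistent agent tracks with continuous margin influx."""
    ac = sg.AgentConfig(n_agents=200, seed=1, dt_min=0.5,
                        D_c=coarse_config.D_c, beta=coarse_config.beta,
                        spawn="influx")
    return sg.sample_agent_tracks(coarse_trajectory, ac)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
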