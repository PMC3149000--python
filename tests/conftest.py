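import logging

import pytest
from hypothesis import HealthCheck, settings

from coliflux.biomass import default_composition_table
from coliflux.network import build_default_network
from coliflux.synth import ScenarioConfig, generate_scenario

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("coliflux").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def net():
    return build_default_network()


@pytest.fixture(scope="session")
def comp_table():
    return default_composition_table()


@pytest.fixture(scope="session")
def astat_clean():
    """Noise-free A-stat scenario with exact ground truth."""
    return generate_scenario(ScenarioConfig(noise_cv=0.0, seed=1))


@pytest.fixture(scope="session")
def astat_noisy():
    """Default 2% measurement noise A-stat scenario, fixed seed."""
    return generate_scenario(ScenarioConfig(noise_cv=0.02, seed=1))


@pytest.fixture(scope="session")
def astat_fixture_path():
    from importlib.resources import files

    return str(files("coliflux").joinpath("data/scenarios/astat_reference.csv"))


@pytest.fixture(scope="session")
def dstat_fixture_paths():
    from importlib.resources import files

    base = files("coliflux").joinpath("data/scenarios")
    return [str(base.joinpath(f"dstat_D{d}.csv"))
            for d in ("0.10", "0.24", "0.30", "0.45")]
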