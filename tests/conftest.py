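import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

from twophase_audit import (ModelSpec, SeedStream, StratumTable, Theta)
from twophase_audit.simulate import SimScenario, scenario_theta

hypothesis_settings.register_profile("repro", derandomize=True, deadline=None)
hypothesis_settings.load_profile("repro")


@pytest.fixture(scope="session")
def base_scenario() -> SimScenario:
    """Base setting: N=10,000, n=400, p_x=0.1, p_y0=0.3, all rates 0.1/0.9."""
    return SimScenario()


@pytest.fixture(scope="session")
def base_spec(base_scenario) -> ModelSpec:
    return base_scenario.model_spec()


@pytest.fixture(scope="session")
def base_theta(base_scenario) -> Theta:
    return scenario_theta(base_scenario)


@pytest.fixture(scope="session")
def toy_strata() -> StratumTable:
    """Small 4-stratum table where exhaustive design enumeration is cheap."""
    return StratumTable.from_mapping(
        {(0, 0, 0): 50, (0, 1, 0): 30, (1, 0, 0): 20, (1, 1, 0): 10})


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def perturbed_thetas(base_theta, base_spec, k: int, scale: float = 0.3,
                     seed: int = 0):
    """Random parameter draws around the base generating value."""
    rng = np.random.default_rng(seed)
    flat = base_theta.flatten(base_spec)
    for _ in range(k):
        yield Theta.from_flat(flat + rng.normal(0.0, scale, flat.size),
                              base_spec)
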