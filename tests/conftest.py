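import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lungtarget.synthetic_lung import (
    SyntheticScenario,
    default_scenario,
    generate_geometry,
    simulate_msi,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_scenario(**overrides) -> SyntheticScenario:
    """A 60x60 one-airway scenario for fast unit tests."""
    params = dict(
        grid_size=(60, 60),
        n_airways=1,
        lumen_radius=(5.0, 6.0),
        n_vessels=1,
        vessel_radius=(2.0, 3.0),
        alveolar_porosity=0.0,
    )
    params.update(overrides)
    return SyntheticScenario(**params)


@pytest.fixture(scope="session")
def default_sc() -> SyntheticScenario:
    return default_scenario()


@pytest.fixture(scope="session")
def small_sc() -> SyntheticScenario:
    return small_scenario()


@pytest.fixture(scope="session")
def small_section(small_sc):
    """One noisy small section with its ground truth (seed 11)."""
    return simulate_msi(small_sc, seed=11)


@pytest.fixture(scope="session")
def small_noiseless_section(small_sc):
    scenario = small_sc.without_noise()
    geometry = generate_geometry(scenario, seed=11)
    return simulate_msi(scenario, geometry=geometry, seed=11)


@pytest.fixture(scope="session")
def default_section(default_sc):
    """One noisy default-scenario section (seed 1), reused across tests."""
    return simulate_msi(default_sc, seed=1)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    return float((a & b).sum() / (a | b).sum())
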