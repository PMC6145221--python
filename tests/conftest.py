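import pytest

from readry import SolverConfig, simulate
from readry.synthetic_data import (
    DRYING_AMBIENT,
    TEMPERING_AMBIENT,
    SyntheticConfig,
    default_geometry,
    default_material,
    default_schedule,
    default_truth,
    generate_experiment,
)
from readry.schedule import build_periodic_schedule


@pytest.fixture(scope="session")
def drying_ambient():
    return DRYING_AMBIENT


@pytest.fixture(scope="session")
def tempering_ambient():
    return TEMPERING_AMBIENT


@pytest.fixture(scope="session")
def material():
    return default_material()


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def truth_model():
    return default_truth()


@pytest.fixture(scope="session")
def continuous_curve(truth_model, material, geometry):
    """Continuous drying run stopped at the shelf-life moisture target."""
    schedule = default_schedule(1800.0, 0.0, 120_000.0)
    return simulate(
        schedule, truth_model, material, geometry, SolverConfig(x_target=0.134)
    )


@pytest.fixture(scope="session")
def intermittent_curve(truth_model, material, geometry):
    """alpha = 0.5 intermittent run stopped at the moisture target."""
    schedule = build_periodic_schedule(
        1800.0, 1800.0, DRYING_AMBIENT, TEMPERING_AMBIENT, 200_000.0
    )
    return simulate(
        schedule, truth_model, material, geometry, SolverConfig(x_target=0.134)
    )


@pytest.fixture(scope="session")
def noisy_experiment():
    """Default continuous synthetic experiment, seed 1, 1% mass noise."""
    cfg = SyntheticConfig(seed=1, noise_mass=0.01, noise_T=0.2)
    measured, truth, clean = generate_experiment(cfg)
    return cfg, measured, truth, clean


@pytest.fixture(scope="session")
def noiseless_experiment():
    cfg = SyntheticConfig(seed=3, noise_mass=0.0, noise_T=0.0)
    measured, truth, clean = generate_experiment(cfg)
    return cfg, measured, truth, clean
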