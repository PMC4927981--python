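import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from atabridge.assay_data import StudyDesign
from atabridge.config import Config, default_config
from atabridge.synthetic import simulate_study

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def config() -> Config:
    return default_config()


@pytest.fixture(scope="session")
def small_design() -> StudyDesign:
    """2 groups x 3 animals x (2 pre + 2 post) — enough structure, tiny."""
    return StudyDesign(
        groups=(("control", 0.0), ("5mg/kg", 5.0)),
        animals_per_group=3,
        pretreatment_days=(-14, -7),
        posttreatment_days=(29, 57),
    )


@pytest.fixture(scope="session")
def small_records(small_design, config):
    return simulate_study(small_design, config.simulation, seed=42)


@pytest.fixture(scope="session")
def small_config(small_design, config) -> Config:
    return dataclasses.replace(config, design=small_design)


@pytest.fixture(scope="session")
def noiseless_config(config) -> Config:
    sim = dataclasses.replace(
        config.simulation, noise_cv=0.0, hinge_within_log_sd=0.0
    )
    return dataclasses.replace(config, simulation=sim)
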