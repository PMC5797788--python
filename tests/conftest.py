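"""Shared fixtures: one full default-scenario run is reused across modules."""

import pytest
from hypothesis import HealthCheck, settings

from tgkit.pipeline import ScenarioConfig, run_default_scenario
from tgkit.synthgen.genome import IntegrationScenario, build_reference_set

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

PLANTED_LEFT = 78_137_441
PLANTED_RIGHT = 78_139_250


@pytest.fixture(scope="session")
def refs_default():
    """References for the default scenario (seed fixed)."""
    return build_reference_set(11)


@pytest.fixture(scope="session")
def default_bundle():
    """One full default homozygous run with artifacts kept."""
    return run_default_scenario(seed=1, keep_artifacts=True)


@pytest.fixture(scope="session")
def wt_bundle():
    """Wild-type negative-control run with artifacts kept."""
    cfg = ScenarioConfig.default_scenario(scenario=IntegrationScenario(zygosity="wt"))
    return run_default_scenario(cfg, seed=1, keep_artifacts=True)


@pytest.fixture(scope="session")
def hemi_bundle():
    """Hemizygous run with artifacts kept."""
    cfg = ScenarioConfig.default_scenario(
        scenario=IntegrationScenario(zygosity="hemizygous")
    )
    return run_default_scenario(cfg, seed=1, keep_artifacts=True)
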