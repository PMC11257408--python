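import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import editscan as es


@pytest.fixture(scope="session")
def design():
    return es.StudyDesign()


@pytest.fixture(scope="session")
def small_study(design):
    """A small study with known planted truth, shared across tests."""
    ref = es.generate_reference(3000, seed=11)
    planted = es.plant_edit_sites(
        ref, 12, f_control_range=(0.05, 0.2), kd_reduction=0.5, seed=11)
    pileups = es.simulate_pileups(ref, planted, design, depth=800, seed=11)
    return ref, planted, pileups
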