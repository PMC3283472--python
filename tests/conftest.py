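import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_template():
    """Reference-patient template (PI 61, SS 52, 30% slip)."""
    from spondylofem.synthetic_data import generate_template_geometry
    return generate_template_geometry()


@pytest.fixture(scope="session")
def small_model(baseline_template):
    """Coarse (resolution 6) detailed mesh of the baseline patient."""
    from spondylofem.synthetic_data import build_detailed_mesh
    return build_detailed_mesh(baseline_template, resolution=6)


@pytest.fixture(scope="session")
def small_solution(small_model):
    """Follower-load equilibrium on the coarse model."""
    from spondylofem.loading import (LoadDistribution,
                                     follower_equilibrium_iteration,
                                     standing_boundary_conditions)
    bcs = standing_boundary_conditions(small_model)
    u, state, diag = follower_equilibrium_iteration(
        small_model, bcs, LoadDistribution(45.5))
    return {"u": u, "state": state, "diag": diag, "bcs": bcs}


@pytest.fixture()
def rng():
    return np.random.default_rng(20120118)
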