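import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240807)


@pytest.fixture(scope="session")
def delta_kernel():
    """Pure local-deposition kernel: all electron energy in the source voxel."""
    from prrtdose import build_parametric_kernel
    return build_parametric_kernel(
        2.0, components={"local_fraction": 1.0, "photon_fraction": 0.0},
        radius_voxels=1)


@pytest.fixture(scope="session")
def spread_kernel():
    """Energy-conserving kernel with a wide beta spread (edge-loss visible)."""
    from prrtdose import build_parametric_kernel
    return build_parametric_kernel(
        2.0, components={"local_fraction": 0.0, "beta_range_mm": 3.0,
                         "photon_fraction": 0.0},
        radius_voxels=7)
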