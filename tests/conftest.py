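import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nettdcs as nt

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def positions_1020():
    return nt.standard_positions("10-20")


@pytest.fixture(scope="session")
def table1_anodal():
    return nt.table1_montage("anodal")


@pytest.fixture(scope="session")
def table1_cathodal():
    return nt.table1_montage("cathodal")


@pytest.fixture(scope="session")
def small_leadfield():
    """12-electrode, 80-sample synthetic lead field for optimizer tests."""
    return nt.synthetic_leadfield(12, n_samples=80, seed=11)


@pytest.fixture(scope="session")
def small_target(small_leadfield):
    rng = np.random.default_rng(7)
    r = np.clip(0.25 * rng.standard_normal(small_leadfield.n_samples), -0.9, 0.9)
    return nt.build_target(nt.FcMap(r=r))


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
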