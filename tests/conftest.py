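import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hepatoscope as hs

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lattice_exact():
    """Jitter-free three-alternate lattice, r0 = 100 µm, 2 mm window."""
    cfg = hs.SyntheticTissueConfig(
        lattice_radius_r0=100.0,
        jitter_sd=0.0,
        portal_occupancy="three_alternate",
        window_width=2000.0,
        window_height=2000.0,
        seed=7,
    )
    return hs.generate_lobular_lattice(cfg)


@pytest.fixture(scope="session")
def lattice_deep(lattice_exact):
    """Same lattice restricted to central veins whose 2·r0 portal shell is
    guaranteed inside the window."""
    return hs.restrict_sources(lattice_exact, hs.CENTRAL, 220.0)


@pytest.fixture(scope="session")
def nuclei_default():
    """Default synthetic nuclear population (~1900 nuclei), seed 0."""
    return hs.generate_nuclei(hs.NucleusPopulationConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
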