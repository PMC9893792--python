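import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from medconn.config import SimulationConfig
from medconn.synthetic import make_parcellation

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_parcellation():
    """Default-config parcellation (some planted sub-20-mm pairs)."""
    return make_parcellation(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def sparse_parcellation():
    """Parcellation with all ROI centers at least 25 mm apart."""
    cfg = SimulationConfig(
        seed=1,
        min_pair_distance=25.0,
        near_pair_fraction=0.0,
        coord_box=(220.0, 220.0, 220.0),
    )
    return make_parcellation(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
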