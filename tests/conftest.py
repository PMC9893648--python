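import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from dropquant import AmplitudeModel, SimulationSpec, simulate_well

#: Midpoint thresholds of the default amplitude model (clusters at 2000/8000).
MIDPOINT = (5000.0, 5000.0)

#: Rain-robust analysis thresholds: 3 SD below the positive cluster (7100 a.u.).
THRESHOLDS = AmplitudeModel().rain_robust_thresholds()


@pytest.fixture
def clean_model():
    """Amplitude model without rain — classification is then exact."""
    return AmplitudeModel(rain_fraction=0.0)


@pytest.fixture
def duplex_well(clean_model):
    """A rain-free 300:100 copies/µL duplex well, fixed seed."""
    spec = SimulationSpec(
        conc_wt=300.0, conc_mut=100.0, amplitude_model=clean_model, seed=42
    )
    return simulate_well(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
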