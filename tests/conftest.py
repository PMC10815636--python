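import math

import pytest
from hypothesis import HealthCheck, settings

from gelphys import GravimetricSeries, NetworkParams, SimConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_params() -> NetworkParams:
    """Constants for PSA-g-mPEG gels in water, densities assumed."""
    return NetworkParams()


@pytest.fixture
def sim_config() -> SimConfig:
    return SimConfig(seed=1)


def first_order_series(
    q_inf: float,
    k: float = 1.5,
    m0: float = 10.0,
    times=None,
    sample_id: str = "s1",
    label: str = "PEG-400",
) -> GravimetricSeries:
    """Noiseless gravimetric series on mt = m0 (1 + q_inf (1 - e^(-k t)))."""
    if times is None:
        times = [float(t) for t in range(25)]
    return GravimetricSeries(
        sample_id=sample_id,
        crosslinker_label=label,
        temperature_c=22.0,
        m0_mg=m0,
        observations=[
            (t, m0 * (1 + q_inf * (1 - math.exp(-k * t)))) for t in times
        ],
    )
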