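import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from excare import DetectionBasis, ReadingSession
from excare.thresholds import CHANNELS

settings.register_profile(
    "repro", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def basis() -> DetectionBasis:
    return DetectionBasis.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_session(
    basis: DetectionBasis,
    deltas_by_cycle,
    session_id: str = "test",
    reads_per_cycle: int = 2,
    true_label=None,
) -> ReadingSession:
    """Noise-free session whose every read sits at baseline + delta."""
    bases = {
        "temperature": basis.baseline_temperature,
        "humidity": basis.baseline_humidity,
        "ammonia": basis.ambient_ammonia,
    }
    reads = {}
    for cycle, (dx, dy, dz) in enumerate(deltas_by_cycle, start=1):
        offs = dict(zip(CHANNELS, (dx, dy, dz)))
        reads[cycle] = {
            ch: [bases[ch] + offs[ch]] * reads_per_cycle for ch in CHANNELS
        }
    return ReadingSession(session_id=session_id, reads=reads, true_label=true_label)
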