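import numpy as np
import pytest

from breathdx import SensorSweep, SimulationConfig


@pytest.fixture
def noiseless_config() -> SimulationConfig:
    """Degenerate generator settings: no noise, no drift, no replicate-1 bias."""
    return SimulationConfig(
        n_cases=2,
        n_controls=2,
        sigma_subject=0.0,
        sigma_replicate=0.0,
        drift_prob=0.0,
        first_replicate_bias=0.0,
        seed=1,
    )


def make_flat_sweep(
    level: float = 100.0,
    n_channels: int = 4,
    sample_rate: float = 5.0,
    peak: float | None = None,
) -> SensorSweep:
    """A constant-resistance sweep, optionally with a plateau during the sample phase."""
    dt = 1.0 / sample_rate
    times = np.arange(0.0, 60.0 + dt / 2, dt)
    resist = np.full((n_channels, times.size), level)
    if peak is not None:
        mask = (times > 10.0) & (times <= 50.0)
        resist[:, mask] = peak
    return SensorSweep(
        subject_id="X",
        replicate=2,
        times=times,
        resistances=resist,
        phase_bounds=(10.0, 50.0, 60.0),
    )


@pytest.fixture
def flat_sweep() -> SensorSweep:
    return make_flat_sweep()
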