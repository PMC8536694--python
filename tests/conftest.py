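import numpy as np
import pytest

from enosedx import CohortConfig, SampleMeta, SensorRecording, simulate_recording

#: tiny hand-written two-sensor recording for exact-value oracle tests
#: (1 Hz; baseline [0,3), during [3,8), after [8,10))
HAND_CURVES = [
    [100.0, 98.0, 99.0, 90.0, 80.0, 72.0, 65.0, 60.0, 70.0, 80.0],
    [50.0, 50.5, 49.5, 48.0, 44.0, 41.0, 40.0, 39.5, 42.0, 46.0],
]
HAND_PHASES = {"baseline": (0, 3), "during": (3, 8), "after": (8, 10)}


def make_hand_recording() -> SensorRecording:
    curves = np.array(HAND_CURVES)
    return SensorRecording(
        time_s=np.arange(curves.shape[1], dtype=float),
        resistance=curves,
        sampling_hz=1.0,
        phases=HAND_PHASES,
        meta=SampleMeta(sample_id="hand", subject_id="hand"),
    )


@pytest.fixture
def hand_recording() -> SensorRecording:
    return make_hand_recording()


def noiseless_config(**overrides) -> CohortConfig:
    """Default study config with every stochastic knob switched off."""
    base = dict(
        noise_sd=0.0,
        amplitude_jitter_sd=0.0,
        subject_sd=0.0,
        day_scale_sd=0.0,
    )
    base.update(overrides)
    return CohortConfig(**base)


@pytest.fixture
def noiseless_recording() -> SensorRecording:
    cfg = noiseless_config()
    meta = SampleMeta(sample_id="nl1", subject_id="nl1", class_label="S")
    return simulate_recording(cfg, meta)


@pytest.fixture(scope="session")
def default_recording() -> SensorRecording:
    """One recording under fully default study conditions (with noise)."""
    cfg = CohortConfig(seed=7)
    meta = SampleMeta(sample_id="d1", subject_id="d1", class_label="PCa")
    return simulate_recording(cfg, meta)
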