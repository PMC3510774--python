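import numpy as np
import pytest

from imuact import (
    CLASS_ORDER,
    ImuRecording,
    SubjectProfile,
    SynthConfig,
    WindowSpec,
    build_dataset,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_recording(rng):
    """10 s, 30 Hz walking recording with mild noise."""
    n = 300
    t = np.arange(n) / 30.0
    accel = 0.3 * np.sin(2 * np.pi * 1.9 * t)[:, None] * np.ones(3)
    accel = accel + rng.normal(0, 0.02, (n, 3))
    gyro = 0.6 * np.sin(2 * np.pi * 1.9 * t + 0.5)[:, None] * np.ones(3)
    gyro = gyro + rng.normal(0, 0.05, (n, 3))
    return ImuRecording(
        participant_id="S01", activity_code="A2", t=t, accel=accel, gyro=gyro
    )


@pytest.fixture
def small_config():
    """Reduced synthetic collection: 4 subjects, 20 s recordings."""
    return SynthConfig(n_subjects=4, duration_s=20.0, seed=11)


@pytest.fixture
def small_dataset(small_config):
    recs = generate_dataset(small_config)
    return build_dataset(recs, WindowSpec(), "accel_gyro")


@pytest.fixture(scope="session")
def default_dataset():
    """Dataset generated under the default study conditions (16 subjects,
    60 s recordings, default class specs and noise), 2 s windows."""
    recs = generate_dataset(SynthConfig(seed=2026))
    return build_dataset(recs, WindowSpec(), "accel_gyro")
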